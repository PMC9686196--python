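#!/usr/bin/env python
"""Enthalpy-entropy decomposition of single-oligomer adsorption.

Builds Lennard-Jones interaction profiles for a coarse oligomer cloud
approaching the reference particle face-on toward a {111} and a {100}
plane at matched surface separation, takes the 54.7- and 0-degree PMFs
from 05 as the free energies, and splits DG = DH - TDS along
xi* = xi - R.  The denser in-plane packing of {111} puts more gold atoms
inside the 1 nm cutoff at equal separation, so the {111} approach shows
the deeper enthalpy well — the packing-factor argument for the facet
preference being enthalpic rather than entropic.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from nanofacet import crystal, freeenergy
from nanofacet.crystal import LatticeSpec, WulffSpec
from nanofacet.io import substream_seed, write_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

gold = LatticeSpec()
particle = crystal.build_wulff_nanoparticle(gold, WulffSpec(0.96, 4.0))
R = particle.radius_estimate

# Generic coarse-site LJ parameters (configuration input, not force-field
# values): shallow site-gold attraction, 1 nm cutoff.
params = freeenergy.LJParams(
    epsilon={"Au": 0.6, "SITE": 0.25},
    sigma={"Au": 0.29, "SITE": 0.35},
    cutoff=1.0,
)

rng = np.random.default_rng(substream_seed(SEED, "thermo"))
# compact rigid site cloud; configurations whose sites come closer to a
# gold atom than the pair sigma are skipped — they sit inside the repulsive
# wall the energy-minimized contact state never crosses
cloud = rng.normal(0.0, 0.08, size=(69, 3))
CLEARANCE = 0.28  # nm, ~ the Au-site LJ sigma

from scipy.spatial import cKDTree

tree = cKDTree(particle.positions)

normals = {"54.7": np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
           "0": np.array([0.0, 0.0, 1.0])}
# surface-separation grid starting just outside the repulsive wall
separations = np.arange(0.50, 1.51, 0.02)  # nm

for name, normal in normals.items():
    d_face = float((particle.positions @ normal).max())
    configs = []
    for sep in separations:
        xi = d_face + sep
        sites = cloud + normal * xi
        if tree.query(sites)[0].min() >= CLEARANCE:
            configs.append((xi, sites))
    dh = freeenergy.lj_energy_profile(configs, particle, params)
    write_table(pd.DataFrame({"xi_nm": dh.xi, "dH_kJmol": dh.energy}),
                OUT / f"enthalpy_theta{name}.csv", seed=SEED)
    pmf_df = pd.read_csv(OUT / "pmf_profiles.csv", comment="#")
    sel = pmf_df[pmf_df.theta_deg == float(name)]
    pmf = freeenergy.PMFProfile(xi=sel.xi_nm.to_numpy(),
                                delta_g=sel.dG_kJmol.to_numpy())
    thermo = freeenergy.decompose_thermo(pmf, dh, R)
    write_table(pd.DataFrame({
        "xi_star_nm": thermo.xi_star,
        "dG_kJmol": thermo.delta_g,
        "dH_kJmol": thermo.delta_h,
        "TdS_kJmol": thermo.t_delta_s,
    }), OUT / f"thermo_theta{name}.csv", seed=SEED)
    print(f"theta={name}: min DG {thermo.delta_g.min():7.2f}, "
          f"min DH {thermo.delta_h.min():7.2f}, "
          f"TdS at contact {thermo.t_delta_s[0]:7.2f} kJ/mol")
print(f"wrote enthalpy and decomposition tables to {OUT}")
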
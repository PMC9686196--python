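"""Shrake-Rupley solvent-accessible surface area with per-facet attribution.

Each atom's SASA is estimated by quadrature: a deterministic golden-spiral
point set is placed on the probe-expanded sphere of radius r_vdw + r_probe,
and the accessible fraction is the fraction of points outside every other
atom's expanded sphere.  Accessible areas of nanoparticle atoms are summed by
facet label; adsorbate sites enter only as occluders.

Relative SASA (coverage) time series reference each facet family's area on
the bare particle, so 100% means fully uncoated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .crystal import BULK, EDGE, F100, F111, FacetedNanoparticle

__all__ = [
    "SASAOptions",
    "SASAResult",
    "CoverageSeries",
    "compute_sasa",
    "per_facet_sasa",
    "facet_exposure",
    "coverage_series",
    "golden_spiral_points",
]

#: van der Waals radii (nm) used when no explicit map is given.
DEFAULT_RADII = {"Au": 0.166}
#: Generic radius for coarse adsorbate sites (nm).
DEFAULT_ADSORBATE_RADIUS = 0.17


@dataclass(frozen=True)
class SASAOptions:
    probe_radius: float = 0.14  # nm (water)
    quadrature_points: int = 960
    radii_map: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    adsorbate_radius: float = DEFAULT_ADSORBATE_RADIUS

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.quadrature_points < 92:
            raise ValueError("need at least 92 quadrature points")


@dataclass
class SASAResult:
    per_atom_area: np.ndarray  # nm^2 per nanoparticle atom
    facet_totals: dict  # label -> nm^2
    total: float  # nm^2


@dataclass
class CoverageSeries:
    times: np.ndarray  # ps
    relative_sasa: dict  # label or "total" -> (n_frames,) percent
    absolute_sasa: dict  # label or "total" -> (n_frames,) nm^2
    bare: SASAResult


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (Fibonacci spiral)."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = golden * i
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def compute_sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    options: SASAOptions = SASAOptions(),
    occluder_positions: np.ndarray | None = None,
    occluder_radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom accessible areas (nm^2).

    ``occluder_positions`` adds atoms that block solvent but whose own areas
    are not reported.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if positions.size == 0:
        raise ValueError("empty input: no atoms to compute SASA for")
    if not np.isfinite(positions).all():
        raise ValueError("positions must be finite")
    if (radii <= 0).any():
        raise ValueError("radii must be positive")

    if occluder_positions is not None and len(occluder_positions):
        occ_pos = np.vstack([positions, np.asarray(occluder_positions, float)])
        occ_rad = np.concatenate([radii, np.asarray(occluder_radii, float)])
    else:
        occ_pos, occ_rad = positions, radii

    probe = options.probe_radius
    expanded = occ_rad + probe
    sphere = golden_spiral_points(options.quadrature_points)
    tree = cKDTree(occ_pos)
    max_exp = expanded.max()

    areas = np.empty(len(positions))
    own_exp = radii + probe
    # Any occluder whose expanded sphere can clip atom i's test sphere lies
    # within own_exp[i] + max_exp of atom i.
    neighbor_lists = tree.query_ball_point(positions, own_exp + max_exp)
    for i, pos in enumerate(positions):
        r = own_exp[i]
        nbrs = [j for j in neighbor_lists[i] if not (j < len(positions) and j == i)]
        test = pos + r * sphere
        if nbrs:
            nb_pos = occ_pos[nbrs]
            nb_exp = expanded[nbrs]
            d2 = ((test[:, None, :] - nb_pos[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 > nb_exp[None, :] ** 2).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r * r * frac
    return areas


def per_facet_sasa(
    particle: FacetedNanoparticle,
    adsorbate_positions: np.ndarray | None = None,
    adsorbate_radii: np.ndarray | float | None = None,
    options: SASAOptions = SASAOptions(),
) -> SASAResult:
    """Facet-attributed SASA of the nanoparticle.

    Adsorbate atoms occlude but are not reported.  Facet totals cover F111,
    F100, EDGE and BULK (the latter ~0 on intact particles).
    """
    labels = particle.facet_labels
    if labels is None or len(labels) != len(particle):
        raise ValueError("particle is missing facet labels")
    element = particle.element
    if element not in options.radii_map:
        raise ValueError(f"no van der Waals radius for element {element!r}")
    radii = np.full(len(particle), options.radii_map[element])

    occ_pos = occ_rad = None
    if adsorbate_positions is not None and len(adsorbate_positions):
        occ_pos = np.asarray(adsorbate_positions, dtype=float)
        if adsorbate_radii is None:
            occ_rad = np.full(len(occ_pos), options.adsorbate_radius)
        elif np.isscalar(adsorbate_radii):
            occ_rad = np.full(len(occ_pos), float(adsorbate_radii))
        else:
            occ_rad = np.asarray(adsorbate_radii, dtype=float)
        # Occluders coincident with particle atoms make the quadrature
        # meaningless for that atom; drop them with a warning.
        tree = cKDTree(particle.positions)
        d, _ = tree.query(occ_pos)
        bad = d < 1e-6
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} adsorbate site(s) coincide with particle "
                "atoms; skipped as occluders",
                stacklevel=2,
            )
            occ_pos, occ_rad = occ_pos[~bad], occ_rad[~bad]

    areas = compute_sasa(
        particle.positions, radii, options,
        occluder_positions=occ_pos, occluder_radii=occ_rad,
    )
    facet_totals = {
        lab: float(areas[labels == lab].sum()) for lab in (F111, F100, EDGE, BULK)
    }
    return SASAResult(
        per_atom_area=areas,
        facet_totals=facet_totals,
        total=float(areas.sum()),
    )


def facet_exposure(result: SASAResult, edge_policy: str = "split") -> dict:
    """Percent of facet-attributed area on each plane family.

    edge_policy "split" apportions each edge atom's area equally to the two
    families (edge atoms border both); "exclude" drops edge area from the
    denominator.  Returns {"F111": pct, "F100": pct}.
    """
    a111 = result.facet_totals.get(F111, 0.0)
    a100 = result.facet_totals.get(F100, 0.0)
    edge = result.facet_totals.get(EDGE, 0.0)
    if edge_policy == "split":
        a111 += 0.5 * edge
        a100 += 0.5 * edge
    elif edge_policy != "exclude":
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    denom = a111 + a100
    if denom == 0:
        raise ValueError("no facet-attributed surface area")
    return {F111: 100.0 * a111 / denom, F100: 100.0 * a100 / denom}


def coverage_series(
    traj,
    particle: FacetedNanoparticle,
    options: SASAOptions = SASAOptions(),
    frame_stride: int = 1,
) -> CoverageSeries:
    """Relative (percent-of-bare) and absolute facet SASA along a trajectory.

    Trajectory frames are in box coordinates with the particle centered at
    box_edge/2; particle coordinates are centered at the origin, so frames
    are shifted before occlusion.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    bare = per_facet_sasa(particle, options=options)
    shift = np.full(3, traj.box_edge / 2.0)
    idx = np.arange(0, traj.n_frames, frame_stride)
    keys = (F111, F100, EDGE)
    absolute = {k: np.empty(len(idx)) for k in (*keys, "total")}
    for out_i, f in enumerate(idx):
        res = per_facet_sasa(
            particle,
            adsorbate_positions=traj.frames[f] - shift,
            options=options,
        )
        for k in keys:
            absolute[k][out_i] = res.facet_totals[k]
        absolute["total"][out_i] = res.total
    bare_ref = {k: bare.facet_totals[k] for k in keys}
    bare_ref["total"] = bare.total
    relative = {
        k: 100.0 * absolute[k] / bare_ref[k] if bare_ref[k] > 0
        else np.full(len(idx), np.nan)
        for k in absolute
    }
    return CoverageSeries(
        times=traj.times[idx],
        relative_sasa=relative,
        absolute_sasa=absolute,
        bare=bare,
    )
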
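"""Free-energy reconstruction and thermodynamic decomposition of adsorption.

Umbrella-sampling windows (harmonically biased samples of the reaction
coordinate xi) are combined by the weighted histogram analysis method
(WHAM): the unbiased distribution P(xi) and per-window free energies f_i are
iterated to self-consistency,

    P_b = sum_i H_ib / sum_i N_i f_i c_ib,     1/f_i = sum_b c_ib P_b,

with c_ib = exp(-beta k_i/2 (xi_b - c_i)^2).  The potential of mean force is
-kBT ln P, anchored to zero at the largest sampled xi, where an adsorbing
oligomer no longer feels the particle.

Orientation-resolved PMFs assemble into a polar free-energy landscape over
(theta, xi).  An enthalpy proxy DH(xi) is the pairwise 12-6 Lennard-Jones
energy of particle-adsorbate configurations (optionally plus Coulomb), and
T*DS follows from the identity DG = DH - T*DS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .crystal import FacetedNanoparticle
from .synthgen import KB_KJ_PER_MOL_K

__all__ = [
    "PMFProfile",
    "PolarFEL",
    "LJParams",
    "ThermoProfiles",
    "EnergyProfile",
    "wham",
    "average_pmfs",
    "assemble_polar_fel",
    "lj_energy_profile",
    "lj_pair_energy",
    "decompose_thermo",
]

#: Coulomb prefactor in kJ mol^-1 nm e^-2.
COULOMB_KJ_NM = 138.935458


@dataclass
class PMFProfile:
    xi: np.ndarray  # nm, strictly increasing
    delta_g: np.ndarray  # kJ/mol, 0 at the largest xi
    std: np.ndarray | None = None  # kJ/mol across replicas
    reference: str = "zero-at-largest-xi"

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.delta_g = np.asarray(self.delta_g, dtype=float)
        if len(self.xi) != len(self.delta_g):
            raise ValueError("xi and delta_g must have equal length")
        if len(self.xi) > 1 and not (np.diff(self.xi) > 0).all():
            raise ValueError("xi grid must be strictly increasing")


@dataclass
class PolarFEL:
    thetas: np.ndarray  # degrees
    xi: np.ndarray  # nm, shared grid
    delta_g: np.ndarray  # (n_theta, n_xi) kJ/mol
    min_theta: float
    min_xi: float
    degenerate_theta: bool = False


@dataclass(frozen=True)
class LJParams:
    """12-6 Lennard-Jones parameters with optional Coulomb term.

    Per-species epsilon (kJ/mol) and sigma (nm) dictionaries; cross terms by
    geometric (epsilon) and arithmetic (sigma) combination unless an explicit
    ``pair_overrides[(a, b)] = (eps, sigma)`` entry exists.
    """

    epsilon: dict
    sigma: dict
    cutoff: float = 1.0  # nm
    charges: dict = field(default_factory=dict)  # species -> e
    pair_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if any(e < 0 for e in self.epsilon.values()):
            raise ValueError("epsilon must be non-negative")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigma must be positive")

    def pair(self, a: str, b: str) -> tuple:
        for key in ((a, b), (b, a)):
            if key in self.pair_overrides:
                return self.pair_overrides[key]
        eps = math.sqrt(self.epsilon[a] * self.epsilon[b])
        sig = 0.5 * (self.sigma[a] + self.sigma[b])
        return eps, sig


@dataclass
class EnergyProfile:
    xi: np.ndarray  # nm, strictly increasing
    energy: np.ndarray  # kJ/mol, 0 at the largest xi


@dataclass
class ThermoProfiles:
    xi_star: np.ndarray  # nm, xi - R_particle
    delta_g: np.ndarray
    delta_h: np.ndarray
    t_delta_s: np.ndarray


def wham(
    windows: list,
    temperature: float = 300.0,
    bin_width: float = 0.005,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    min_counts: int = 25,
) -> PMFProfile:
    """Self-consistent WHAM over harmonically biased windows.

    Adjacent windows (ordered by center) must share at least one occupied
    histogram bin; otherwise the offending gap is reported.  Convergence is
    measured by the largest change in the per-window free energies in kBT.

    Bins with fewer than ``min_counts`` total samples are solved over but
    excluded from the reported profile: the Poisson error of -kBT ln P in a
    bin with n samples is ~kBT/sqrt(n), so thinly sampled tail bins carry
    multi-kJ/mol noise that would swamp the profile.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not windows:
        raise ValueError("no umbrella windows given")
    windows = sorted(windows, key=lambda w: w.center)
    kbt = KB_KJ_PER_MOL_K * temperature
    beta = 1.0 / kbt

    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])

    hists = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows],
                     dtype=float)
    n_samples = hists.sum(axis=1)

    occupied = [set(np.flatnonzero(h > 0).tolist()) for h in hists]
    for i in range(len(windows) - 1):
        if not (occupied[i] & occupied[i + 1]):
            raise ValueError(
                "no histogram overlap between windows centered at "
                f"{windows[i].center:g} and {windows[i + 1].center:g} nm"
            )

    # Bin-averaged Boltzmann factor of each harmonic bias: with k as stiff as
    # 10^4 kJ/mol/nm^2 the bias varies strongly across a bin, so the exact
    # Gaussian integral over the bin replaces the midpoint value.
    c = np.empty((len(windows), n_bins))
    for i, w in enumerate(windows):
        s = math.sqrt(1.0 / (beta * w.force_constant))
        z_hi = (edges[1:] - w.center) / (s * math.sqrt(2.0))
        z_lo = (edges[:-1] - w.center) / (s * math.sqrt(2.0))
        from scipy.special import erf
        c[i] = (s * math.sqrt(math.pi / 2.0) * (erf(z_hi) - erf(z_lo))
                / bin_width)
    c = np.clip(c, 1e-300, None)

    total = hists.sum(axis=0)

    # The self-consistent equations are the stationarity conditions of a
    # convex likelihood in the window free energies g_i = ln f_i; minimizing
    # it first makes the subsequent fixed-point iteration converge at once
    # even when window overlap is thin.
    from scipy.optimize import minimize

    occ = total > 0
    log_c = np.log(c[:, occ])
    m_b = total[occ]

    def objective(gv):
        logits = np.log(n_samples)[:, None] + gv[:, None] + log_c
        lse = np.logaddexp.reduce(logits, axis=0)
        val = float((m_b * lse).sum() - (n_samples * gv).sum())
        w = np.exp(logits - lse[None, :])
        grad = (m_b[None, :] * w).sum(axis=1) - n_samples
        return val, grad

    res = minimize(objective, np.zeros(len(windows)), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    g = res.x - res.x[0]

    for _ in range(max_iter):
        denom = (n_samples[:, None] * np.exp(g)[:, None] * c).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        norm = (c * p[None, :]).sum(axis=1)
        g_new = -np.log(norm)
        g_new -= g_new[0]
        residual = np.abs(g_new - g).max()
        g = g_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge in {max_iter} iterations "
            f"(residual {residual:.3e} kBT)"
        )

    keep = total >= max(1, min_counts)
    if not keep.any():
        keep = total > 0
    xi = centers[keep]
    dg = -kbt * np.log(p[keep])
    dg -= dg[-1]  # anchor at the largest sampled xi
    return PMFProfile(xi=xi, delta_g=dg)


def average_pmfs(pmfs: list) -> PMFProfile:
    """Mean and standard deviation of replica PMFs on their common support."""
    if len(pmfs) < 1:
        raise ValueError("need at least one PMF")
    lo = max(p.xi.min() for p in pmfs)
    hi = min(p.xi.max() for p in pmfs)
    if lo >= hi:
        raise ValueError("replica PMFs have disjoint xi ranges")
    step = min(np.diff(p.xi).min() for p in pmfs)
    grid = np.arange(lo, hi + step / 2, step)
    curves = np.array([np.interp(grid, p.xi, p.delta_g) for p in pmfs])
    curves -= curves[:, -1:]  # re-anchor on the common grid
    return PMFProfile(
        xi=grid,
        delta_g=curves.mean(axis=0),
        std=curves.std(axis=0),
    )


def assemble_polar_fel(pmfs: dict) -> PolarFEL:
    """Combine orientation-resolved PMFs {theta_deg: PMFProfile} into a
    polar free-energy landscape on a shared xi grid."""
    if len(pmfs) < 2:
        raise ValueError("need at least two orientations")
    thetas = np.array(sorted(pmfs), dtype=float)
    lo = max(pmfs[t].xi.min() for t in thetas)
    hi = min(pmfs[t].xi.max() for t in thetas)
    if lo >= hi:
        raise ValueError("PMFs have disjoint xi ranges")
    step = min(min(np.diff(pmfs[t].xi).min() for t in thetas), (hi - lo) / 50)
    grid = np.arange(lo, hi + step / 2, step)
    matrix = np.array([np.interp(grid, pmfs[t].xi, pmfs[t].delta_g) for t in thetas])

    flat = int(np.argmin(matrix))
    i_theta, i_xi = np.unravel_index(flat, matrix.shape)
    per_theta_min = matrix.min(axis=1)
    degenerate = int((per_theta_min <= matrix.min() + 1e-9).sum()) > 1
    return PolarFEL(
        thetas=thetas,
        xi=grid,
        delta_g=matrix,
        min_theta=float(thetas[i_theta]),
        min_xi=float(grid[i_xi]),
        degenerate_theta=degenerate,
    )


def lj_pair_energy(r: np.ndarray, eps: float, sigma: float) -> np.ndarray:
    """4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def lj_energy_profile(
    configurations,
    particle: FacetedNanoparticle,
    params: LJParams,
    adsorbate_species: str = "SITE",
    adsorbate_charges: np.ndarray | None = None,
) -> EnergyProfile:
    """Particle-adsorbate interaction energy along the reaction coordinate.

    ``configurations`` is a sequence of ``(xi, adsorbate_positions)`` pairs,
    adsorbate coordinates in the particle frame (particle centered at the
    origin).  Pairs beyond ``params.cutoff`` do not contribute.  The profile
    is referenced to zero at the largest xi.
    """
    if not configurations:
        raise ValueError("no configurations given")
    el = particle.element
    eps, sigma = params.pair(el, adsorbate_species)
    q_np = params.charges.get(el, 0.0)
    tree = cKDTree(particle.positions)
    xis = np.array([float(c[0]) for c in configurations])
    energies = np.empty(len(configurations))
    for k, (_, sites) in enumerate(configurations):
        sites = np.asarray(sites, dtype=float)
        pairs = tree.query_ball_point(sites, params.cutoff)
        e = 0.0
        for s_idx, np_idx in enumerate(pairs):
            if not np_idx:
                continue
            r = np.linalg.norm(particle.positions[np_idx] - sites[s_idx], axis=1)
            if (r < 1e-12).any():
                raise ValueError("overlapping sites: zero particle-adsorbate distance")
            e += lj_pair_energy(r, eps, sigma).sum()
            if q_np != 0.0 and adsorbate_charges is not None:
                e += (COULOMB_KJ_NM * q_np * adsorbate_charges[s_idx] / r).sum()
        energies[k] = e
    order = np.argsort(xis)
    xis, energies = xis[order], energies[order]
    energies -= energies[-1]
    return EnergyProfile(xi=xis, energy=energies)


def decompose_thermo(
    pmf: PMFProfile,
    enthalpy: EnergyProfile,
    particle_radius: float,
) -> ThermoProfiles:
    """Split adsorption free energy into enthalpic and entropic parts.

    T*DS(xi*) = DH(xi*) - DG(xi*) with xi* = xi - R_particle; all three
    curves re-anchored to zero at the largest shared xi*, so the identity
    DG - DH + T*DS = 0 holds pointwise by construction.
    """
    lo = max(pmf.xi.min(), enthalpy.xi.min())
    hi = min(pmf.xi.max(), enthalpy.xi.max())
    if lo >= hi:
        raise ValueError("PMF and enthalpy profiles have disjoint xi support")
    grid = pmf.xi[(pmf.xi >= lo) & (pmf.xi <= hi)]
    dg = np.interp(grid, pmf.xi, pmf.delta_g)
    dh = np.interp(grid, enthalpy.xi, enthalpy.energy)
    dg -= dg[-1]
    dh -= dh[-1]
    tds = dh - dg
    return ThermoProfiles(
        xi_star=grid - particle_radius,
        delta_g=dg,
        delta_h=dh,
        t_delta_s=tds,
    )
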
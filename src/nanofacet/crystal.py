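"""Wulff-constructed FCC nanocrystals and crystallographic utilities.

The equilibrium (Wulff) shape of a crystal places each facet family at a
distance from the particle center proportional to its surface energy.  For a
gold particle truncated along the {100} and {111} families the shape is fixed
by the single ratio gamma_{111}/gamma_{100}; the particle mass is fixed by
requiring that the number of FCC lattice atoms matches, as closely as the
discrete lattice allows, the atom content of a sphere of a given equivalent
diameter.

Surface atoms are classified by coordination number within the first
neighbor shell: CN 12 -> bulk, CN 9 -> {111} terrace, CN 8 -> {100} terrace,
any other under-coordinated atom -> edge/vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "BULK",
    "F111",
    "F100",
    "EDGE",
    "LatticeSpec",
    "WulffSpec",
    "MillerPlane",
    "FacetedNanoparticle",
    "build_wulff_nanoparticle",
    "classify_atoms",
    "atomic_packing_factor",
    "interplanar_angle",
    "rotate_particle",
    "equivalent_diameter",
    "default_neighbor_cutoff",
]

# Facet labels (per-atom classification).
BULK = "BULK"
F111 = "F111"
F100 = "F100"
EDGE = "EDGE"

#: Default neighbor-shell cutoff for gold (a = 0.4078 nm); lies strictly
#: between the first (a/sqrt(2) = 0.288 nm) and second (a = 0.408 nm) shells.
GOLD_LATTICE_CONSTANT = 0.4078
GOLD_NEIGHBOR_CUTOFF = 0.34


@dataclass(frozen=True)
class LatticeSpec:
    """Bravais lattice of the particle.  Only FCC is supported."""

    element: str = "Au"
    lattice_constant: float = GOLD_LATTICE_CONSTANT  # nm
    structure: str = "fcc"

    def __post_init__(self) -> None:
        if self.lattice_constant <= 0:
            raise ValueError("lattice_constant must be positive")
        if self.structure.lower() != "fcc":
            raise ValueError(f"unsupported structure {self.structure!r}: FCC only")

    @property
    def nearest_neighbor_distance(self) -> float:
        return self.lattice_constant / math.sqrt(2.0)

    @property
    def atom_volume(self) -> float:
        """Volume per atom in the FCC lattice (4 atoms per cubic cell), nm^3."""
        return self.lattice_constant**3 / 4.0


@dataclass(frozen=True)
class WulffSpec:
    """Shape parameters of the truncated particle.

    gamma_ratio is gamma_{111}/gamma_{100}; target_diameter is the equivalent
    spherical diameter (nm) fixing the particle mass.
    """

    gamma_ratio: float = 0.96
    target_diameter: float = 4.0
    plane_families: tuple = ((1, 0, 0), (1, 1, 1))

    def __post_init__(self) -> None:
        if self.gamma_ratio <= 0:
            raise ValueError("gamma_ratio must be positive")
        if self.target_diameter <= 0:
            raise ValueError("target_diameter must be positive")
        for fam in self.plane_families:
            fam_key = tuple(sorted(abs(int(h)) for h in fam))
            if fam_key not in ((0, 0, 1), (1, 1, 1)):
                raise ValueError(f"unsupported plane family {fam}")


@dataclass(frozen=True)
class MillerPlane:
    """A crystallographic plane given by integer Miller indices."""

    indices: tuple

    def __post_init__(self) -> None:
        idx = tuple(int(h) for h in self.indices)
        if len(idx) != 3 or not any(idx):
            raise ValueError("Miller indices must be a nonzero integer triple")
        object.__setattr__(self, "indices", idx)

    @property
    def family(self) -> tuple:
        return tuple(sorted(abs(h) for h in self.indices))

    @property
    def normal(self) -> np.ndarray:
        n = np.asarray(self.indices, dtype=float)
        return n / np.linalg.norm(n)


@dataclass
class FacetedNanoparticle:
    """An FCC cluster with per-atom facet labels, centered at its centroid."""

    positions: np.ndarray  # (N, 3) nm
    element: str
    facet_labels: np.ndarray  # (N,) of {BULK, F111, F100, EDGE}
    lattice: LatticeSpec
    radius_estimate: float = field(default=0.0)  # nm, half equivalent diameter

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.positions) < 1:
            raise ValueError("particle must contain at least one atom")
        self.facet_labels = np.asarray(self.facet_labels, dtype="U4")
        if len(self.facet_labels) != len(self.positions):
            raise ValueError("one facet label per atom required")
        if not self.radius_estimate:
            self.radius_estimate = equivalent_diameter(self) / 2.0

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def surface_mask(self) -> np.ndarray:
        return self.facet_labels != BULK

    def facet_counts(self) -> dict:
        labels, counts = np.unique(self.facet_labels, return_counts=True)
        out = {lab: 0 for lab in (BULK, F111, F100, EDGE)}
        out.update(dict(zip(labels.tolist(), counts.tolist())))
        return out


def default_neighbor_cutoff(lattice: LatticeSpec) -> float:
    """Shell cutoff in nm, scaled from the 0.34 nm gold default."""
    return GOLD_NEIGHBOR_CUTOFF * lattice.lattice_constant / GOLD_LATTICE_CONSTANT


def _family_normals(family: tuple) -> np.ndarray:
    """All symmetry-equivalent unit normals of a {100} or {111} family."""
    key = tuple(sorted(abs(int(h)) for h in family))
    if key == (0, 0, 1):
        dirs = []
        for ax in range(3):
            for s in (1.0, -1.0):
                v = np.zeros(3)
                v[ax] = s
                dirs.append(v)
        return np.array(dirs)
    if key == (1, 1, 1):
        return np.array([s for s in product((1.0, -1.0), repeat=3)]) / math.sqrt(3.0)
    raise ValueError(f"unsupported plane family {family}")


def _fcc_lattice_points(lattice: LatticeSpec, half_width: float) -> np.ndarray:
    """FCC lattice points (one atom at the origin) filling a cube of the
    given half-width, in nm."""
    a = lattice.lattice_constant
    m = int(math.ceil(2.0 * half_width / a)) + 1
    rng = np.arange(-m, m + 1)
    i, j, k = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = (i + j + k) % 2 == 0
    pts = np.stack([i[keep], j[keep], k[keep]], axis=1) * (a / 2.0)
    inside = np.all(np.abs(pts) <= half_width + 1e-12, axis=1)
    return pts[inside]


def build_wulff_nanoparticle(
    lattice: LatticeSpec, spec: WulffSpec
) -> FacetedNanoparticle:
    """Build the mass-matched Wulff cluster for {100}/{111} truncation.

    Every FCC lattice point has a critical polyhedron scale at which it
    enters the Wulff shape; sweeping that scale gives the full staircase of
    achievable cluster sizes, from which the one whose atom count is nearest
    the target mass is selected (ties broken toward the smaller cluster).

    The target mass is the number of lattice atoms whose total volume
    (N * a^3 / 4) equals a sphere of ``spec.target_diameter``.
    """
    a = lattice.lattice_constant
    n_target = (math.pi / 6.0) * spec.target_diameter**3 / lattice.atom_volume
    if n_target < 1.0:
        raise ValueError("target below minimal cluster: diameter smaller than one atom")

    # Enumeration window: generous bound on the farthest vertex of any
    # mass-matched {100}/{111} polyhedron (cube half-diagonal ~0.70 d).
    half_width = 0.75 * spec.target_diameter + a
    pts = _fcc_lattice_points(lattice, half_width)

    n100 = _family_normals((1, 0, 0))
    n111 = _family_normals((1, 1, 1))
    # Distance ratios: d_111/d_100 = gamma_ratio (gamma_100 normalized to 1).
    m100 = np.abs(pts @ n100.T).max(axis=1)
    m111 = np.abs(pts @ n111.T).max(axis=1)
    critical_scale = np.maximum(m100, m111 / spec.gamma_ratio)

    order = np.argsort(critical_scale, kind="stable")
    s_sorted = critical_scale[order]
    # Plateau counts at each distinct critical scale (symmetry orbits enter
    # together, so counts jump by whole orbits).
    uniq = np.unique(np.round(s_sorted, 9))
    plateau_counts = np.searchsorted(s_sorted, uniq + 1e-9, side="right")
    gap = np.abs(plateau_counts - n_target)
    best = int(np.flatnonzero(gap == gap.min())[0])  # tie -> smaller cluster
    n_atoms = int(plateau_counts[best])

    positions = pts[order[:n_atoms]]
    positions = positions - positions.mean(axis=0)

    # The polyhedron's {100} half-width equals the selected scale; if it
    # reaches the enumeration window the staircase was truncated.
    if uniq[best] >= half_width - a / 2.0:
        raise RuntimeError("enumeration window too small for requested shape")

    particle = FacetedNanoparticle(
        positions=positions,
        element=lattice.element,
        facet_labels=np.full(n_atoms, EDGE, dtype="U4"),
        lattice=lattice,
    )
    particle.facet_labels = classify_atoms(particle)
    return particle


def classify_atoms(
    particle: FacetedNanoparticle, neighbor_cutoff: float | None = None
) -> np.ndarray:
    """Label atoms by first-shell coordination number.

    CN 12 -> BULK, CN 9 -> F111, CN 8 -> F100, anything else -> EDGE.  The
    cutoff must fall strictly between the first (a/sqrt(2)) and second (a)
    neighbor shells.
    """
    lattice = particle.lattice
    if neighbor_cutoff is None:
        neighbor_cutoff = default_neighbor_cutoff(lattice)
    first = lattice.nearest_neighbor_distance
    second = lattice.lattice_constant
    if not (first < neighbor_cutoff < second):
        raise ValueError(
            "ambiguous shell cutoff: "
            f"{neighbor_cutoff} nm not in ({first:.4f}, {second:.4f}) nm"
        )
    cn = coordination_numbers(particle.positions, neighbor_cutoff)
    labels = np.full(len(cn), EDGE, dtype="U4")
    labels[cn == 12] = BULK
    labels[cn == 9] = F111
    labels[cn == 8] = F100
    return labels


def coordination_numbers(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """Neighbor counts within ``cutoff`` for every atom (excluding itself)."""
    positions = np.asarray(positions, dtype=float)
    tree = cKDTree(positions)
    counts = tree.query_ball_point(positions, cutoff, return_length=True)
    return np.asarray(counts, dtype=int) - 1


def atomic_packing_factor(plane: MillerPlane) -> float:
    """2D packing fraction of touching-sphere cross sections in the plane.

    The {111} plane is a hexagonal (triangular) net, pi/(2*sqrt(3)) ~ 0.907;
    the {100} plane is a square net, pi/4 ~ 0.785.
    """
    fam = plane.family
    if fam == (1, 1, 1):
        return math.pi / (2.0 * math.sqrt(3.0))
    if fam == (0, 0, 1):
        return math.pi / 4.0
    raise ValueError(f"unsupported plane family {plane.indices}")


def interplanar_angle(a: MillerPlane, b: MillerPlane) -> float:
    """Angle between plane normals, in degrees, folded into [0, 90]."""
    cosang = abs(float(np.dot(a.normal, b.normal)))
    return math.degrees(math.acos(min(1.0, cosang)))


def rotate_particle(
    particle: FacetedNanoparticle, axis: np.ndarray, theta: float
) -> FacetedNanoparticle:
    """Rigid rotation by ``theta`` degrees about ``axis`` through the centroid."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be nonzero")
    rot = Rotation.from_rotvec(axis / norm * math.radians(theta))
    return FacetedNanoparticle(
        positions=rot.apply(particle.positions),
        element=particle.element,
        facet_labels=particle.facet_labels.copy(),
        lattice=particle.lattice,
        radius_estimate=particle.radius_estimate,
    )


def equivalent_diameter(particle_or_n, lattice: LatticeSpec | None = None) -> float:
    """Equivalent spherical diameter (nm): d = (6 N a^3 / (4 pi))^(1/3)."""
    if isinstance(particle_or_n, FacetedNanoparticle):
        n = len(particle_or_n)
        lattice = particle_or_n.lattice
    else:
        n = int(particle_or_n)
        if lattice is None:
            raise ValueError("lattice required when passing an atom count")
    if n < 1:
        raise ValueError("empty particle")
    return (6.0 * n * lattice.atom_volume / math.pi) ** (1.0 / 3.0)
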
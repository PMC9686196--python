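"""PLGA oligomer composition at formula level, and coarse site-cloud placement.

A poly(lactic-co-glycolic acid) chain is an ester copolymer of lactic (LA,
residue C3H4O2) and glycolic (GA, residue C2H2O2) units; chain termination
adds H and OH caps (one water equivalent) in the protonated (acid) state.
The reference oligomer here is 6 LA + 2 GA (75:25), i.e. 566 g/mol and 69
atoms including hydrogens.

Downstream analyses (clustering, surface coverage) only consume atom
positions, so an oligomer is represented spatially as a cloud of point
sites — one per atom — around its center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResidueSpec",
    "OligomerSpec",
    "build_plga",
    "molecular_weight",
    "atom_count",
    "chemical_formula",
    "place_oligomers",
    "molar_concentration_mm",
]

# Standard atomic masses, g/mol.
ATOMIC_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999}

# Ester residue formulas (element -> count).
RESIDUE_FORMULAS = {
    "LA": {"C": 3, "H": 4, "O": 2},
    "GA": {"C": 2, "H": 2, "O": 2},
}

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class ResidueSpec:
    """One monomer unit in the chain."""

    kind: str  # "LA" | "GA"
    is_terminal_head: bool = False  # carries the extra H cap
    is_terminal_tail: bool = False  # carries the OH cap

    def __post_init__(self) -> None:
        if self.kind not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue kind {self.kind!r}")


@dataclass(frozen=True)
class OligomerSpec:
    """An ordered residue sequence plus protonation state."""

    sequence: tuple
    protonated: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("oligomer must contain at least one residue")
        for i, res in enumerate(self.sequence):
            if res.is_terminal_head and i != 0:
                raise ValueError("head cap allowed on the first residue only")
            if res.is_terminal_tail and i != len(self.sequence) - 1:
                raise ValueError("tail cap allowed on the last residue only")

    @property
    def sequence_string(self) -> str:
        return " ".join("L" if r.kind == "LA" else "G" for r in self.sequence)

    def residue_counts(self) -> dict:
        counts = {"LA": 0, "GA": 0}
        for res in self.sequence:
            counts[res.kind] += 1
        return counts


def build_plga(
    n_la: int, n_ga: int, protonated: bool = True, sequence: str | None = None
) -> OligomerSpec:
    """Build a PLGA chain of ``n_la`` LA and ``n_ga`` GA residues.

    The default arrangement is a block copolymer (all LA then all GA); an
    explicit ``sequence`` string such as ``"LLLGLLLG"`` overrides it.
    Composition-level quantities (mass, atom count) do not depend on the
    arrangement.
    """
    if n_la < 0 or n_ga < 0 or n_la + n_ga < 1:
        raise ValueError("chain must contain at least one residue")
    if sequence is None:
        kinds = ["LA"] * n_la + ["GA"] * n_ga
    else:
        letters = [c for c in sequence.upper() if not c.isspace()]
        kinds = ["LA" if c == "L" else "GA" for c in letters]
        if any(c not in "LG" for c in letters):
            raise ValueError("sequence may contain only L and G")
        if kinds.count("LA") != n_la or kinds.count("GA") != n_ga:
            raise ValueError("sequence does not match residue counts")
    residues = tuple(
        ResidueSpec(
            kind=k,
            is_terminal_head=(i == 0),
            is_terminal_tail=(i == len(kinds) - 1),
        )
        for i, k in enumerate(kinds)
    )
    return OligomerSpec(sequence=residues, protonated=protonated)


def chemical_formula(o: OligomerSpec) -> dict:
    """Element counts of the whole chain including caps."""
    formula = {"C": 0, "H": 0, "O": 0}
    for res in o.sequence:
        for el, n in RESIDUE_FORMULAS[res.kind].items():
            formula[el] += n
    # Chain termination: H + OH caps when protonated; the deprotonated
    # (carboxylate) chain is short one acid hydrogen.
    formula["H"] += 2 if o.protonated else 1
    formula["O"] += 1
    return formula


def molecular_weight(o: OligomerSpec) -> float:
    """Molar mass in g/mol from standard atomic masses."""
    return sum(ATOMIC_MASSES[el] * n for el, n in chemical_formula(o).items())


def atom_count(o: OligomerSpec) -> int:
    """Total atom count including hydrogens (9/LA, 6/GA, +3 caps protonated)."""
    return sum(chemical_formula(o).values())


def place_oligomers(
    n: int,
    box_edge: float,
    sites_per_oligomer: int = 69,
    gyration_radius: float = 0.5,
    min_separation: float = 1.5,
    seed=None,
    avoid_center_radius: float = 0.0,
    max_tries: int = 10_000,
):
    """Random initial configuration of ``n`` oligomer site clouds.

    Centers are drawn uniformly in a periodic cubic box of edge ``box_edge``
    (coordinates in [0, L)), rejected until all pairs are at least
    ``min_separation`` apart under the minimum-image convention, and
    optionally kept outside a central sphere of ``avoid_center_radius``
    (e.g. the nanoparticle).  Each oligomer is a cloud of
    ``sites_per_oligomer`` points uniform in a sphere of ``gyration_radius``
    about its center.

    Returns ``(sites, centers)`` with shapes (n*sites_per_oligomer, 3) and
    (n, 3); reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one oligomer")
    exclusion = (4.0 / 3.0) * np.pi * (min_separation / 2.0) ** 3
    if n * exclusion >= box_edge**3:
        raise ValueError("infeasible packing: exclusion volume exceeds the box")
    rng = np.random.default_rng(seed)
    half = box_edge / 2.0
    centers = np.empty((n, 3))
    placed = 0
    for _ in range(max_tries * n):
        if placed == n:
            break
        cand = rng.uniform(0.0, box_edge, size=3)
        if avoid_center_radius > 0.0:
            if np.linalg.norm(cand - half) < avoid_center_radius:
                continue
        if placed:
            delta = np.abs(centers[:placed] - cand)
            delta = np.minimum(delta, box_edge - delta)
            if (np.linalg.norm(delta, axis=1) < min_separation).any():
                continue
        centers[placed] = cand
        placed += 1
    if placed < n:
        raise ValueError("infeasible packing: could not place all oligomers")

    # Uniform-in-sphere clouds around each center.
    m = n * sites_per_oligomer
    directions = rng.normal(size=(m, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = gyration_radius * rng.uniform(0.0, 1.0, size=(m, 1)) ** (1.0 / 3.0)
    sites = np.repeat(centers, sites_per_oligomer, axis=0) + directions * radii
    return np.mod(sites, box_edge), centers


def molar_concentration_mm(n_molecules: int, box_edge: float) -> float:
    """Concentration in mM of ``n_molecules`` in a cubic box of edge nm."""
    volume_liters = (box_edge**3) * 1e-24
    return n_molecules / (AVOGADRO * volume_liters) * 1e3
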
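"""Structure, trajectory and table I/O plus run configuration.

Internal units are nm / ps / kJ/mol / K everywhere.  XYZ files are written
and read with coordinates in nm (declared in the comment line, which also
carries a JSON metadata tag for the lattice constant and facet labels); GRO
is natively nm.  Tabular outputs are CSV with a commented header recording
the package version, seed and a hash of the generating parameters, so
deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crystal import EDGE, FacetedNanoparticle, LatticeSpec, classify_atoms
from .synthgen import BindingEvent, MergeEvent, SyntheticTrajectory, UmbrellaWindow

__all__ = [
    "RunConfig",
    "substream_seed",
    "write_xyz",
    "read_xyz",
    "write_particle_xyz",
    "read_particle_xyz",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_gro",
    "read_gro",
    "write_truth_log",
    "write_facet_budget",
    "write_umbrella_windows",
    "read_umbrella_windows",
    "write_table",
]

PACKAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Seed, units and stage parameters of one pipeline run."""

    seed: int = 0
    units: dict = field(default_factory=lambda: {
        "length": "nm", "time": "ps", "energy": "kJ/mol", "temperature": "K",
    })
    out_dir: str = "results"
    params: dict = field(default_factory=dict)


def substream_seed(seed: int, stage: str) -> int:
    """Named, collision-resistant substream seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, params=None) -> None:
    """CSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# nanofacet {PACKAGE_VERSION}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if params is not None:
            fh.write(f"# params_hash: {_params_hash(params)}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, positions, elements, comment: str = "", mode: str = "w") -> None:
    positions = np.asarray(positions, dtype=float)
    if np.isscalar(elements) or isinstance(elements, str):
        elements = [elements] * len(positions)
    with open(path, mode) as fh:
        fh.write(f"{len(positions)}\n")
        fh.write(comment.replace("\n", " ") + "\n")
        for el, (x, y, z) in zip(elements, positions):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz_block(lines, start):
    try:
        natoms = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"malformed atom count at line {start + 1}")
    comment = lines[start + 1] if start + 1 < len(lines) else None
    if comment is None or start + 2 + natoms > len(lines):
        raise ValueError(f"truncated XYZ block starting at line {start + 1}")
    elements, coords = [], np.empty((natoms, 3))
    for i in range(natoms):
        ln = start + 2 + i
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"malformed atom record at line {ln + 1}")
        elements.append(parts[0])
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ValueError(f"malformed coordinate at line {ln + 1}")
    return elements, coords, comment, start + 2 + natoms


def read_xyz(path):
    """Single-frame XYZ -> (positions nm, elements, comment)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty XYZ file at line 1")
    elements, coords, comment, _ = _read_xyz_block(lines, 0)
    return coords, elements, comment


def write_particle_xyz(path, particle: FacetedNanoparticle,
                       seed=None) -> None:
    meta = {
        "units": "nm",
        "lattice_constant": particle.lattice.lattice_constant,
        "facet_labels": particle.facet_labels.tolist(),
    }
    if seed is not None:
        meta["seed"] = seed
    write_xyz(
        path,
        particle.positions,
        particle.element,
        comment=json.dumps(meta),
    )


def read_particle_xyz(path) -> FacetedNanoparticle:
    coords, elements, comment = read_xyz(path)
    labels = None
    lattice_constant = LatticeSpec().lattice_constant
    try:
        meta = json.loads(comment)
        labels = meta.get("facet_labels")
        lattice_constant = meta.get("lattice_constant", lattice_constant)
    except (json.JSONDecodeError, AttributeError):
        pass
    lattice = LatticeSpec(element=elements[0], lattice_constant=lattice_constant)
    particle = FacetedNanoparticle(
        positions=coords,
        element=elements[0],
        facet_labels=np.asarray(labels, dtype="U4") if labels is not None
        else np.full(len(coords), EDGE, dtype="U4"),
        lattice=lattice,
    )
    if labels is None:
        particle.facet_labels = classify_atoms(particle)
    return particle


def write_trajectory_xyz(path, traj: SyntheticTrajectory,
                         element: str = "C") -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_sites}\n")
            fh.write(
                f"t= {traj.times[f]:.3f} ps box= {traj.box_edge:.6f} nm\n"
            )
            for (x, y, z) in traj.frames[f]:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory_xyz(path):
    """Multi-frame XYZ -> (frames, times ps, box_edge nm)."""
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    box = None
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        _, coords, comment, pos = _read_xyz_block(lines, pos)
        frames.append(coords)
        tokens = comment.split()
        t = b = None
        for i, tok in enumerate(tokens):
            if tok == "t=" and i + 1 < len(tokens):
                t = float(tokens[i + 1])
            if tok == "box=" and i + 1 < len(tokens):
                b = float(tokens[i + 1])
        times.append(t if t is not None else float(len(times)))
        box = b if b is not None else box
    if not frames:
        raise ValueError("no frames found in trajectory file")
    return np.array(frames), np.array(times), box


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def write_gro(path, positions, elements, box_edge: float,
              title: str = "nanofacet structure") -> None:
    positions = np.asarray(positions, dtype=float)
    if np.isscalar(elements) or isinstance(elements, str):
        elements = [elements] * len(positions)
    with open(path, "w") as fh:
        fh.write(title.replace("\n", " ") + "\n")
        fh.write(f"{len(positions)}\n")
        for i, (el, (x, y, z)) in enumerate(zip(elements, positions), start=1):
            resname = (el[:3] or "UNK").upper()
            fh.write(
                f"{i % 100000:5d}{resname:<5s}{el[:5]:>5s}{i % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{box_edge:10.5f}{box_edge:10.5f}{box_edge:10.5f}\n")


def read_gro(path):
    """GRO file -> (positions nm, atom names, box edge nm)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("truncated GRO file at line 1")
    try:
        natoms = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise ValueError("malformed atom count at line 2")
    if len(lines) < natoms + 3:
        raise ValueError(f"truncated GRO file: expected {natoms} atoms, "
                         f"file ends at line {len(lines)}")
    coords = np.empty((natoms, 3))
    names = []
    for i in range(natoms):
        ln = lines[2 + i]
        try:
            names.append(ln[10:15].strip())
            coords[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except (ValueError, IndexError):
            raise ValueError(f"malformed GRO record at line {i + 3}")
    try:
        box = float(lines[2 + natoms].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"malformed box vector at line {natoms + 3}")
    return coords, names, box


# ---------------------------------------------------------------------------
# Truth logs, budgets, umbrella windows
# ---------------------------------------------------------------------------

def write_truth_log(path, traj: SyntheticTrajectory) -> None:
    """Ground-truth merge/binding events as TSV
    (frame, event, oligomer_id, facet)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("frame\tevent\toligomer_id\tfacet\n")
        for ev in traj.events:
            if isinstance(ev, BindingEvent):
                for o in ev.members:
                    fh.write(f"{ev.frame}\tbind\t{o}\t{ev.facet}\n")
            elif isinstance(ev, MergeEvent):
                for o in ev.members:
                    fh.write(f"{ev.frame}\tmerge\t{o}\t\n")


def write_facet_budget(path, particle: FacetedNanoparticle,
                       sasa_result=None, seed=None) -> None:
    """Per-label atom counts and (optionally) SASA area shares as CSV."""
    counts = particle.facet_counts()
    rows = []
    for label, n in counts.items():
        share = ""
        if sasa_result is not None and sasa_result.total > 0:
            share = sasa_result.facet_totals.get(label, 0.0) / sasa_result.total
        rows.append({"label": label, "atom_count": n, "area_share": share})
    write_table(pd.DataFrame(rows), path, seed=seed)


def write_umbrella_windows(directory, windows, temperature: float,
                           seed=None) -> None:
    """One two-column text file (index, xi nm) per window + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"temperature_K": temperature, "windows": []}
    if seed is not None:
        manifest["seed"] = seed
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        np.savetxt(
            directory / fname,
            np.column_stack([np.arange(len(w.samples)), w.samples]),
            fmt=("%d", "%.8f"),
        )
        manifest["windows"].append({
            "file": fname,
            "center_nm": w.center,
            "force_constant_kJ_mol_nm2": w.force_constant,
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_umbrella_windows(directory):
    """Read windows written by :func:`write_umbrella_windows`.

    Returns (list of UmbrellaWindow, temperature K).
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    windows = []
    for entry in manifest["windows"]:
        data = np.loadtxt(directory / entry["file"])
        windows.append(UmbrellaWindow(
            center=float(entry["center_nm"]),
            force_constant=float(entry["force_constant_kJ_mol_nm2"]),
            samples=np.atleast_2d(data)[:, 1],
        ))
    return windows, float(manifest["temperature_K"])
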
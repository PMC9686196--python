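"""Cluster-count kinetics and radial distribution analyses.

Oligomer aggregation is tracked by density-based clustering of atom sites
frame by frame.  The production path delegates to HDBSCAN
(scikit-learn) with the hyperparameters used throughout this project:
min_samples=7, min_cluster_size=60, manhattan metric, leaf cluster
selection.  A plain fixed-radius DBSCAN lives alongside it as an independent
reference implementation for validation on planted partitions.

Radial profiles come in two flavors: a conventional g(r) of sites around a
reference point (normalized by shell volume and mean density, -> 1 for an
ideal gas) and an unnormalized site-site distance distribution g*(r)
(shell-volume normalization only), whose short-range part reflects the rigid
intramolecular geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN

__all__ = [
    "ClusteringParams",
    "ClusterCountSeries",
    "RDFProfile",
    "count_clusters",
    "cluster_count_series",
    "rdf_to_reference",
    "pair_distance_distribution",
    "dbscan_fixed_radius",
    "minimum_image_cityblock",
]


@dataclass(frozen=True)
class ClusteringParams:
    min_samples: int = 7
    min_cluster_size: int = 60
    metric: str = "manhattan"
    selection: str = "leaf"  # "leaf" | "eom"
    periodic: bool = True  # minimum-image distances when a box edge is known

    def __post_init__(self) -> None:
        if self.min_samples < 1 or self.min_cluster_size < 1:
            raise ValueError("min_samples and min_cluster_size must be >= 1")
        if self.metric not in ("manhattan", "euclidean"):
            raise ValueError("metric must be manhattan or euclidean")
        if self.selection not in ("leaf", "eom"):
            raise ValueError("selection must be leaf or eom")


@dataclass
class ClusterCountSeries:
    times: np.ndarray  # ps
    n_clusters_mean: np.ndarray
    n_clusters_std: np.ndarray
    per_replica: np.ndarray  # (n_replicas, n_frames)


@dataclass
class RDFProfile:
    r_centers: np.ndarray  # nm
    values: np.ndarray
    bin_width: float
    raw_counts: np.ndarray | None = None


def minimum_image_cityblock(points: np.ndarray, box_edge: float) -> np.ndarray:
    """Pairwise manhattan distances under the minimum-image convention."""
    points = np.asarray(points, dtype=float)
    out = np.zeros((len(points), len(points)))
    for d in range(points.shape[1]):
        delta = np.abs(points[:, d, None] - points[None, :, d])
        np.minimum(delta, box_edge - delta, out=delta)
        out += delta
    return out


def _minimum_image_euclidean(points: np.ndarray, box_edge: float) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    acc = np.zeros((len(points), len(points)))
    for d in range(points.shape[1]):
        delta = np.abs(points[:, d, None] - points[None, :, d])
        np.minimum(delta, box_edge - delta, out=delta)
        acc += delta**2
    return np.sqrt(acc)


def count_clusters(
    frame_sites: np.ndarray,
    params: ClusteringParams = ClusteringParams(),
    box_edge: float | None = None,
):
    """Density-based cluster count and labels for one frame of sites.

    Returns ``(n_clusters, labels)`` with -1 marking noise; noise points are
    not counted.  Nanoparticle atoms must not be part of the input.

    Leaf selection cannot select the hierarchy root, so a frame whose sites
    have all merged into one dense cluster would come back as pure noise;
    when leaf selection labels everything noise, an excess-of-mass pass with
    ``allow_single_cluster`` handles that degenerate regime.
    """
    sites = np.asarray(frame_sites, dtype=float)
    if sites.ndim != 2 or len(sites) < 1:
        raise ValueError("need at least one site")
    if len(sites) < params.min_cluster_size:
        return 0, np.full(len(sites), -1)

    if params.periodic and box_edge is not None:
        x = (
            minimum_image_cityblock(sites, box_edge)
            if params.metric == "manhattan"
            else _minimum_image_euclidean(sites, box_edge)
        )
        metric = "precomputed"
    else:
        x, metric = sites, params.metric

    def run(selection, single):
        model = HDBSCAN(
            min_samples=params.min_samples,
            min_cluster_size=params.min_cluster_size,
            metric=metric,
            cluster_selection_method=selection,
            allow_single_cluster=single,
            copy=True,
        )
        return model.fit_predict(x)

    labels = run(params.selection, False)
    if (labels == -1).all():
        labels = run("eom", True)
    n_clusters = int(len(set(labels.tolist()) - {-1}))
    return n_clusters, labels


def cluster_count_series(
    trajectories,
    params: ClusteringParams = ClusteringParams(),
    frame_stride: int = 1,
) -> ClusterCountSeries:
    """Per-frame cluster counts, averaged over replica trajectories.

    ``trajectories`` is one SyntheticTrajectory or a sequence of replicas
    sharing times and box.
    """
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    if len(trajectories) < 1:
        raise ValueError("need at least one replica")
    idx = np.arange(0, trajectories[0].n_frames, frame_stride)
    counts = np.empty((len(trajectories), len(idx)))
    for r, traj in enumerate(trajectories):
        for out_i, f in enumerate(idx):
            n, _ = count_clusters(traj.frames[f], params, box_edge=traj.box_edge)
            counts[r, out_i] = n
    return ClusterCountSeries(
        times=trajectories[0].times[idx],
        n_clusters_mean=counts.mean(axis=0),
        n_clusters_std=counts.std(axis=0),
        per_replica=counts,
    )


def dbscan_fixed_radius(
    points: np.ndarray,
    eps: float,
    min_pts: int,
    box_edge: float | None = None,
    metric: str = "euclidean",
):
    """Plain fixed-radius DBSCAN, written directly from the textbook
    definition; the reference implementation used to validate the
    hierarchical clustering path.

    Returns labels with -1 for noise.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if box_edge is not None:
        dist = (
            minimum_image_cityblock(points, box_edge)
            if metric == "manhattan"
            else _minimum_image_euclidean(points, box_edge)
        )
    else:
        dist = cdist(points, points, metric="cityblock" if metric == "manhattan" else metric)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    stack.append(int(k))
        cluster += 1
    return labels


def _min_image_dist(delta: np.ndarray, box: float) -> np.ndarray:
    delta = delta - box * np.round(delta / box)
    return np.linalg.norm(delta, axis=-1)


def rdf_to_reference(
    traj,
    reference_point: np.ndarray,
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RDFProfile:
    """g(r) of trajectory sites around a fixed reference point.

    Normalized by shell volume and by the mean site density, so a uniform
    ideal gas gives 1 at all r.  Minimum-image distances; r_max must not
    exceed half the box edge.
    """
    box = traj.box_edge
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-12:
        raise ValueError("r_max exceeds half the box edge (minimum image)")
    frames = np.asarray(traj.frames, dtype=float)
    if frames.size == 0:
        raise ValueError("empty trajectory")
    ref = np.asarray(reference_point, dtype=float)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for frame in frames:
        d = _min_image_dist(frame - ref, box)
        h, _ = np.histogram(d, bins=edges)
        counts += h
    counts /= len(frames)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    density = frames.shape[1] / box**3
    values = counts / (shell_vol * density)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(r_centers=centers, values=values, bin_width=bin_width,
                      raw_counts=counts)


def pair_distance_distribution(
    traj,
    bin_width: float = 0.05,
    r_max: float | None = None,
    frame_stride: int = 1,
) -> RDFProfile:
    """Unnormalized site-site distance distribution g*(r).

    All distinct site pairs are histogrammed per frame and divided by shell
    volume only (no mean-density normalization), then averaged over frames.
    The short-range region (r below the intramolecular scale) depends only
    on the rigid cloud geometry, not on the frame.
    """
    box = traj.box_edge
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-12:
        raise ValueError("r_max exceeds half the box edge (minimum image)")
    frames = np.asarray(traj.frames, dtype=float)[::frame_stride]
    if frames.size == 0:
        raise ValueError("empty trajectory")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    raw_total = np.zeros(len(edges) - 1)
    for frame in frames:
        n = len(frame)
        # chunked pair distances to bound memory
        h = np.zeros(len(edges) - 1)
        chunk = max(1, 20_000_000 // max(n, 1))
        for start in range(0, n, chunk):
            block = frame[start:start + chunk]
            delta = block[:, None, :] - frame[None, :, :]
            delta -= box * np.round(delta / box)
            d = np.sqrt((delta**2).sum(axis=2))
            # mask keeps each unordered pair once
            mask = np.zeros_like(d, dtype=bool)
            cols = np.arange(n)
            for bi in range(len(block)):
                mask[bi, cols > start + bi] = True
            hh, _ = np.histogram(d[mask], bins=edges)
            h += hh
        raw_total += h
        counts += h
    counts /= len(frames)
    raw_total /= len(frames)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(
        r_centers=centers,
        values=counts / shell_vol,
        bin_width=bin_width,
        raw_counts=raw_total,
    )
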
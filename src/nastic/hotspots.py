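"""Hotspots: recurrent clustering at the same membrane location.

A hotspot is a group of two or more clusters whose spatial centroids fall
within a small distance eps of each other — "clusters of clusters". With
MinPts = 2, density clustering of the centroids is exactly the connected
components of the eps-neighbour graph, which is how it is computed here.
The conservative default eps is half the average cluster radius. A Monte
Carlo null (centroids uniform over the analysis area) quantifies how much
overlap pure chance would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

from .core import Cluster


@dataclass
class Hotspot:
    hotspot_id: int
    member_cluster_ids: list[int]  # sorted by cluster mean_time
    center: tuple[float, float]
    intercluster_times: list[float]  # successive gaps between member mean_times

    @property
    def n(self) -> int:
        return len(self.member_cluster_ids)


def _centroids(clusters: Sequence[Cluster]) -> np.ndarray:
    return np.array([[c.centroid_x, c.centroid_y] for c in clusters])


def default_eps(clusters: Sequence[Cluster], fraction: float = 0.5) -> float:
    """fraction × mean cluster radius."""
    return fraction * float(np.mean([c.radius for c in clusters]))


def detect_hotspots(
    clusters: Sequence[Cluster], eps: float | None = None, min_pts: int = 2
) -> list[Hotspot]:
    """Group cluster centroids within eps into hotspots (>= min_pts members).

    Equivalent to DBSCAN(eps, MinPts=2) on the centroids; implemented as
    connected components of the <= eps pairwise-distance graph.
    """
    if not clusters:
        return []
    if eps is None:
        eps = default_eps(clusters)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    pts = _centroids(clusters)
    pairs = cKDTree(pts).query_pairs(eps, output_type="ndarray")
    n = len(clusters)
    graph = (
        coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        if len(pairs)
        else coo_matrix((n, n))
    )
    _, comp = _cc(graph, directed=False)
    hotspots = []
    hid = 1
    for c in np.unique(comp):
        idx = np.flatnonzero(comp == c)
        if len(idx) < min_pts:
            continue
        members = sorted((clusters[i] for i in idx), key=lambda cl: cl.mean_time)
        times = [cl.mean_time for cl in members]
        center = pts[idx].mean(axis=0)
        hotspots.append(
            Hotspot(
                hid,
                [cl.cluster_id for cl in members],
                (float(center[0]), float(center[1])),
                list(np.diff(times)),
            )
        )
        hid += 1
    return hotspots


def overlap_probability(points: np.ndarray, eps: float) -> float:
    """1 − (centroids with no neighbour within eps) / (total centroids)."""
    if len(points) < 2:
        return 0.0
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    nn = dist[:, 1]
    return float(1.0 - np.mean(nn > eps))


def overlap_probability_curve(
    clusters: Sequence[Cluster], eps_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Overlap probability at each eps; non-decreasing in eps."""
    pts = _centroids(clusters)
    return [(float(e), overlap_probability(pts, float(e))) for e in eps_grid]


def monte_carlo_null(
    n_clusters: int,
    roi_area: float,
    eps_grid: Sequence[float],
    n_reps: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Null overlap-probability curve for uniformly scattered centroids.

    n_clusters centroids are dropped uniformly on a square of the given
    area, n_reps times; returns (mean, SEM) per eps across replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    side = float(np.sqrt(roi_area))
    probs = np.zeros((n_reps, len(eps_grid)))
    for rep in range(n_reps):
        pts = rng.uniform(0.0, side, size=(n_clusters, 2))
        for j, eps in enumerate(eps_grid):
            probs[rep, j] = overlap_probability(pts, float(eps))
    mean = probs.mean(axis=0)
    sem = probs.std(axis=0, ddof=1) / np.sqrt(n_reps)
    return mean, sem


def nearest_neighbor_null(n_clusters: int, roi_area: float, eps_grid) -> np.ndarray:
    """Poisson nearest-neighbour approximation of the null curve:
    P(NN <= eps) ≈ 1 − exp(−λ π eps² (n−1)/n), λ = n/area (edge effects
    ignored)."""
    lam = n_clusters / roi_area
    eps = np.asarray(eps_grid, dtype=float)
    return 1.0 - np.exp(-lam * np.pi * eps**2 * (n_clusters - 1) / n_clusters)


def hotspot_metrics(hotspots: Sequence[Hotspot]) -> tuple[float, float]:
    """(mean membership, mean intercluster time in s) across hotspots.

    Intercluster time averages the successive gaps between the time-sorted
    member cluster mean-times within each hotspot, then across hotspots.
    """
    if not hotspots:
        return 0.0, float("nan")
    membership = float(np.mean([h.n for h in hotspots]))
    per_hotspot = [float(np.mean(h.intercluster_times)) for h in hotspots]
    return membership, float(np.mean(per_hotspot))


def cluster_rate_timeline(
    clusters: Sequence[Cluster],
    trajectories: dict,
    acquisition: float,
    roi_area: float,
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Clusters present per time bin, normalised per µm².

    A cluster is present in a bin if its detection-time span intersects the
    bin. Returns (bin left edges, counts / roi_area).
    """
    edges = np.arange(0.0, acquisition + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for cl in clusters:
        times = np.concatenate([trajectories[tid].t for tid in cl.member_traj_ids])
        start, end = float(times.min()), float(times.max())
        lo = int(np.floor(start / bin_width))
        hi = int(np.floor(end / bin_width))
        lo = max(lo, 0)
        hi = min(hi, len(counts) - 1)
        counts[lo : hi + 1] += 1
    return edges[:-1], counts / roi_area
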
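"""Baseline spatial clusterers and label-agreement scores.

DBSCAN and Voronoï tessellation of trajectory centroids are the two purely
spatial methods spatiotemporal clustering is compared against. Both adopt
the same "three or more proximal centroids" cluster definition. Agreement
with a ground-truth labelling is scored by the adjusted Rand index (all
unclustered trajectories pooled into one noise class) and the mean
best-match intersection-over-union across true clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import Voronoi
from shapely.geometry import Polygon
from sklearn.cluster import DBSCAN
from sklearn.metrics import adjusted_rand_score


@dataclass(frozen=True)
class LabelScore:
    ari: float  # ∈ [−1, 1]
    mean_iou: float  # ∈ [0, 1]


def dbscan_centroids(
    centroids: np.ndarray, eps: float, min_pts: int = 3, min_cluster_size: int = 3
) -> np.ndarray:
    """Density clustering of 2D centroids; −1 marks unclustered.

    Clusters smaller than min_cluster_size are demoted to noise to match
    the three-centroid cluster definition.
    """
    if eps <= 0 or min_pts < 2:
        raise ValueError("eps must be > 0 and min_pts >= 2")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(np.asarray(centroids))
    for lab in np.unique(labels):
        if lab >= 0 and np.sum(labels == lab) < min_cluster_size:
            labels[labels == lab] = -1
    return labels


def _tile_area(vor: Voronoi, point_idx: int) -> float:
    """Area of a bounded Voronoï tile; inf for unbounded tiles."""
    region = vor.regions[vor.point_region[point_idx]]
    if -1 in region or len(region) < 3:
        return float("inf")
    return Polygon(vor.vertices[region]).area


def voronoi_centroids(
    centroids: np.ndarray, tile_area_threshold: float, min_cluster_size: int = 3
) -> np.ndarray:
    """Voronoï-tessellation clustering of 2D centroids; −1 marks unclustered.

    Centroids with bounded tiles smaller than the threshold are candidates;
    clusters are ridge-sharing (edge, not vertex) connected components of
    candidate tiles with at least min_cluster_size members. Unbounded
    boundary tiles are never clustered.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 4:
        raise ValueError("need >= 4 centroids for a Voronoi tessellation")
    if tile_area_threshold <= 0:
        raise ValueError("tile_area_threshold must be > 0")
    try:
        vor = Voronoi(pts)
    except Exception as exc:  # qhull degeneracy (e.g. collinear input)
        raise ValueError("degenerate centroid configuration for Voronoi") from exc
    areas = np.array([_tile_area(vor, i) for i in range(len(pts))])
    candidate = areas < tile_area_threshold

    n = len(pts)
    edges = [
        (a, b)
        for (a, b) in vor.ridge_points
        if candidate[a] and candidate[b]
    ]
    labels = np.full(n, -1, dtype=int)
    if edges:
        arr = np.array(edges)
        graph = coo_matrix((np.ones(len(arr)), (arr[:, 0], arr[:, 1])), shape=(n, n))
        _, comp = _cc(graph, directed=False)
        next_label = 0
        for c in np.unique(comp[candidate]):
            idx = np.flatnonzero(candidate & (comp == c))
            if len(idx) >= min_cluster_size:
                labels[idx] = next_label
                next_label += 1
    return labels


def score_labels(
    predicted: dict[int, int | None], true: dict[int, int | None]
) -> LabelScore:
    """ARI and mean best-match IoU between two labelings of one universe.

    Unclustered (None) trajectories share a single noise class for the ARI.
    Mean IoU averages, over true clusters, the best Jaccard overlap of the
    cluster's member set with any predicted cluster.
    """
    if set(predicted) != set(true):
        raise ValueError("predicted and true labelings cover different trajectories")
    ids = sorted(true)
    NOISE = -1

    def to_array(labels: dict[int, int | None]) -> np.ndarray:
        return np.array([NOISE if labels[i] is None else labels[i] for i in ids])

    ari = float(adjusted_rand_score(to_array(true), to_array(predicted)))

    true_sets: dict[int, set[int]] = {}
    pred_sets: dict[int, set[int]] = {}
    for tid in ids:
        if true[tid] is not None:
            true_sets.setdefault(true[tid], set()).add(tid)
        if predicted[tid] is not None:
            pred_sets.setdefault(predicted[tid], set()).add(tid)
    if not true_sets:
        return LabelScore(ari, float("nan"))
    ious = []
    for members in true_sets.values():
        best = 0.0
        for pred in pred_sets.values():
            inter = len(members & pred)
            if inter:
                best = max(best, inter / len(members | pred))
        ious.append(best)
    return LabelScore(ari, float(np.mean(ious)))
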
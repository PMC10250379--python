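"""Segment-level spatiotemporal clustering (segNASTIC).

Instead of one box per trajectory, each displacement segment gets its own
bounding box (the x/y extent of its two endpoints, extruded in time around
the segment mid-time). Because segments vastly outnumber trajectories and
most overlap only with siblings of the same molecule, segments are first
thresholded by how many segments *from other trajectories* they overlap;
the mean overlap count — the inflection point of the typically L-shaped
overlap histogram — is the automatic threshold. Clusters of thresholded
segments delimit tighter regions of true molecular overlap than whole
trajectory hulls, which is what makes this variant suited to dense or
long-trajectory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from ._index import overlap_counts, query_box_overlaps
from .core import Cluster, ClusterParams, _hull_of
from .features import Segment, extract_segments
from .io import Trajectory, filter_min_steps


@dataclass
class SegmentBoxes:
    segments: list[Segment]
    traj_ids: np.ndarray  # parent trajectory of each box
    bounds: np.ndarray  # (n, 6)


@dataclass
class SegClusterResult:
    clusters: list[Cluster]  # member_traj_ids = distinct parent trajectories
    cluster_segments: list[list[int]]  # indices into .segments per cluster
    segments: list[Segment]
    overlap_counts: np.ndarray
    threshold: float
    summary: dict = field(default_factory=dict)


def segment_boxes(segments: Sequence[Segment], time_window: float = 20.0) -> SegmentBoxes:
    """One 3D box per segment: spatial min/max of its endpoints (zero-width
    extents kept as-is), time = mid-time ± t/2."""
    n = len(segments)
    bounds = np.empty((n, 6))
    traj_ids = np.empty(n, dtype=int)
    half_t = time_window / 2.0
    for k, seg in enumerate(segments):
        mid = seg.mid_time
        bounds[k] = (
            min(seg.x1, seg.x2),
            max(seg.x1, seg.x2),
            min(seg.y1, seg.y2),
            max(seg.y1, seg.y2),
            mid - half_t,
            mid + half_t,
        )
        traj_ids[k] = seg.traj_id
    return SegmentBoxes(list(segments), traj_ids, bounds)


def segment_overlap_counts(boxes: SegmentBoxes) -> np.ndarray:
    """Per segment, the number of spatiotemporally overlapping boxes of
    segments belonging to *other* trajectories."""
    return overlap_counts(boxes.bounds, group=boxes.traj_ids)


def auto_threshold(counts: np.ndarray) -> float:
    """The automatic candidate threshold: the mean segment overlap.

    Segments are cluster candidates iff their count is strictly greater
    than this (ties at the mean are non-candidates).
    """
    if len(counts) == 0:
        raise ValueError("no segments")
    return float(np.mean(counts))


def run_segnastic(
    trajectories: Sequence[Trajectory],
    params: ClusterParams = ClusterParams(),
    min_steps: int = 8,
    threshold: float | None = None,
) -> SegClusterResult:
    """Cluster above-threshold segments by box overlap.

    A segment cluster is accepted if its segments originate from at least
    ``min_members`` distinct parent trajectories; its hull spans the
    detections bounding the clustered segments. Cluster ids ascend with
    mean segment mid-time.
    """
    selected = filter_min_steps(trajectories, min_steps) if min_steps else list(trajectories)
    segments = [s for tr in selected for s in extract_segments(tr)]
    boxes = segment_boxes(segments, params.time_window)
    counts = segment_overlap_counts(boxes)
    thr = auto_threshold(counts) if threshold is None else threshold
    cand = np.flatnonzero(counts > thr)

    clusters: list[Cluster] = []
    cluster_segments: list[list[int]] = []
    if len(cand):
        pairs = query_box_overlaps(boxes.bounds[cand])
        n = len(cand)
        graph = (
            coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
            if len(pairs)
            else coo_matrix((n, n))
        )
        _, comp = _cc(graph, directed=False)
        for c in np.unique(comp):
            seg_idx = cand[comp == c]
            parents = sorted(set(boxes.traj_ids[seg_idx].tolist()))
            if len(parents) < params.min_members:
                continue
            pts = np.array(
                [
                    pt
                    for k in seg_idx
                    for pt in (
                        (segments[k].x1, segments[k].y1),
                        (segments[k].x2, segments[k].y2),
                    )
                ]
            )
            hull, area, radius = _hull_of(pts)
            mids = np.array([segments[k].mid_time for k in seg_idx])
            times = np.array(
                [tt for k in seg_idx for tt in (segments[k].t1, segments[k].t2)]
            )
            clusters.append(
                Cluster(
                    cluster_id=-1,
                    member_traj_ids=[int(p) for p in parents],
                    hull=hull,
                    area=area,
                    radius=radius,
                    centroid_x=float(pts[:, 0].mean()),
                    centroid_y=float(pts[:, 1].mean()),
                    mean_time=float(mids.mean()),
                    lifetime=float(times.max() - times.min()),
                )
            )
            cluster_segments.append([int(k) for k in seg_idx])

    order = sorted(range(len(clusters)), key=lambda i: clusters[i].mean_time)
    clusters = [clusters[i] for i in order]
    cluster_segments = [cluster_segments[i] for i in order]
    for k, cl in enumerate(clusters, start=1):
        cl.cluster_id = k

    clustered_parents = {tid for cl in clusters for tid in cl.member_traj_ids}
    summary = {
        "selected_trajectories": len(selected),
        "total_segments": len(segments),
        "segment_overlap_threshold": thr,
        "candidate_fraction": float(len(cand) / len(segments)) if segments else 0.0,
        "total_clusters": len(clusters),
        "clustered_trajectories": len(clustered_parents),
        "radius_um": float(np.mean([c.radius for c in clusters])) if clusters else 0.0,
    }
    return SegClusterResult(clusters, cluster_segments, segments, counts, thr, summary)
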
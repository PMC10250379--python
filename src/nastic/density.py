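"""Spatiotemporal inhomogeneity statistics.

If apparent hotspots were just random close encounters, the arrival times
of trajectories at any fixed membrane location would be uniform over the
acquisition. This module finds candidate locations as local maxima of a
Gaussian kernel density estimate of the trajectory centroids, collects the
trajectories within a small radius of each maximum into a "temporal
column", and applies a one-sample Kolmogorov–Smirnov test of the member
temporal centroids against uniformity, Bonferroni-corrected across
columns at a 1% family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde, kstest


@dataclass
class TemporalColumn:
    column_id: int
    center: tuple[float, float]
    member_traj_ids: list[int]
    times: np.ndarray  # member temporal centroids, s
    ks_p: float = float("nan")
    significant: bool = False


def kde_local_maxima(
    centroids: np.ndarray,
    grid_spacing: float = 0.05,
    bandwidth: str | float = "scott",
    prominence_factor: float = 0.0,
) -> np.ndarray:
    """Local maxima of a Gaussian KDE of 2D centroids on a regular grid.

    A maximum is a grid point strictly greater than all 8 neighbours.
    ``prominence_factor`` > 0 additionally requires the density to exceed
    that multiple of the mean grid density, suppressing the shallow maxima
    a uniform scatter produces. Returns an (m, 2) array of (x, y).
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 10:
        raise ValueError("need >= 10 centroids for a KDE")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    if np.any(np.asarray(kde.factor) <= 0):
        raise ValueError("bandwidth must be > 0")
    pad = 2 * grid_spacing
    xs = np.arange(pts[:, 0].min() - pad, pts[:, 0].max() + pad, grid_spacing)
    ys = np.arange(pts[:, 1].min() - pad, pts[:, 1].max() + pad, grid_spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)

    core = dens[1:-1, 1:-1]
    higher = np.ones_like(core, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            shifted = dens[1 + di : dens.shape[0] - 1 + di, 1 + dj : dens.shape[1] - 1 + dj]
            higher &= core > shifted
    if prominence_factor > 0:
        higher &= core > prominence_factor * dens.mean()
    ii, jj = np.nonzero(higher)
    return np.column_stack([xs[ii + 1], ys[jj + 1]])


def build_columns(
    traj_ids: Sequence[int],
    centroids: np.ndarray,
    centroid_times: np.ndarray,
    maxima: np.ndarray,
    radius: float = 0.2,
    min_occupancy: int = 7,
) -> list[TemporalColumn]:
    """One temporal column per density maximum.

    Members are the trajectories whose spatial centroid lies within
    ``radius`` of the maximum; columns with fewer than ``min_occupancy``
    members are dropped. A trajectory may belong to several columns.
    """
    traj_ids = list(traj_ids)
    pts = np.asarray(centroids, dtype=float)
    times = np.asarray(centroid_times, dtype=float)
    tree = cKDTree(pts)
    columns = []
    cid = 1
    for mx in np.atleast_2d(maxima):
        idx = tree.query_ball_point(mx, radius)
        if len(idx) < min_occupancy:
            continue
        idx = sorted(idx)
        columns.append(
            TemporalColumn(
                cid,
                (float(mx[0]), float(mx[1])),
                [traj_ids[i] for i in idx],
                times[idx],
            )
        )
        cid += 1
    return columns


def ks_uniformity(
    columns: Sequence[TemporalColumn],
    acquisition_span: tuple[float, float],
    fwer: float = 0.01,
) -> list[TemporalColumn]:
    """KS test of each column's member times against Uniform(t_min, t_max).

    A column is significant iff p < fwer / (number of columns) (Bonferroni).
    The uniform support is the full acquisition span, not the column's own
    time range. Zero-variance time vectors get the smallest positive float
    as their p-value.
    """
    if not columns:
        return []
    t_min, t_max = acquisition_span
    span = t_max - t_min
    if span <= 0:
        raise ValueError("empty acquisition span")
    threshold = fwer / len(columns)
    for col in columns:
        if np.ptp(col.times) == 0:
            col.ks_p = np.finfo(float).tiny
        else:
            col.ks_p = float(
                kstest(col.times, lambda x: np.clip((x - t_min) / span, 0, 1)).pvalue
            )
        col.significant = col.ks_p < threshold
    return list(columns)
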
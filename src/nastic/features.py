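"""Per-trajectory geometry and mobility features.

Every downstream analysis — the spatiotemporal clusterers, the MSD
pre-filter, the confinement validator — consumes the quantities computed
here: the spatiotemporal centroid, the convex-hull area and its
area-equivalent ("approximate") radius, the time-averaged MSD curve, the
instantaneous diffusion coefficient, the MSD anomalous exponent alpha, and
the per-segment decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .io import Trajectory


@dataclass
class Segment:
    """The displacement between two consecutive detections of one trajectory."""

    traj_id: int
    index: int
    x1: float
    y1: float
    t1: float
    x2: float
    y2: float
    t2: float

    @property
    def mid_time(self) -> float:
        return 0.5 * (self.t1 + self.t2)

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)


@dataclass
class TrajFeatures:
    traj_id: int
    centroid_x: float
    centroid_y: float
    centroid_t: float
    hull_area: float  # µm²
    approx_radius: float  # µm
    msd_lags: np.ndarray = field(default_factory=lambda: np.empty(0))  # s
    msd: np.ndarray = field(default_factory=lambda: np.empty(0))  # µm²
    d_inst: float = float("nan")  # µm²/s
    alpha: float = float("nan")
    n_steps: int = 0

    @property
    def msd_scalar(self) -> float:
        """Per-trajectory MSD summary used by the density pre-filter.

        Mean of the first four MSD values (the same window as ``d_inst``);
        falls back to the mean of whatever lags exist for short trajectories.
        """
        if len(self.msd) == 0:
            return float("nan")
        return float(np.mean(self.msd[:4]))


def spatiotemporal_centroid(trajectory: Trajectory) -> tuple[float, float, float]:
    """Unweighted mean position in space and time."""
    return trajectory.centroid()


def hull_area_and_radius(
    trajectory: Trajectory, radius_mode: str = "area"
) -> tuple[float, float]:
    """Convex-hull area (µm²) and approximate radius (µm) of a trajectory.

    The approximate radius is the radius of the circle with the same area as
    the hull, ``sqrt(area / π)`` (``radius_mode="area"``), or half the
    maximum pairwise detection distance (``radius_mode="maxdist"``).
    Degenerate hulls (fewer than 3 non-collinear detections) get area 0 and
    the half-max-distance fallback so every trajectory still receives a
    usable bounding box.
    """
    pts = trajectory.xy
    area = 0.0
    if len(pts) >= 3:
        try:
            area = float(ConvexHull(pts).volume)  # 2D: volume == area
        except QhullError:
            area = 0.0
    if radius_mode == "maxdist" or area == 0.0:
        radius = float(pdist(pts).max() / 2.0) if len(pts) >= 2 else 0.0
        if radius_mode == "area" and area > 0.0:
            radius = math.sqrt(area / math.pi)
    else:
        radius = math.sqrt(area / math.pi)
    return area, radius


def msd_curve(
    trajectory: Trajectory, max_lags: int | None = None, uniform_tol: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean square displacement.

    msd(nΔ) = ⟨(x_{i+n} − x_i)² + (y_{i+n} − y_i)²⟩ over all valid i, for
    n = 1..min(max_lags, n_steps), with Δ the (median) frame interval.
    Returns (lags in s, msd in µm²).
    """
    n = trajectory.n_detections
    if n < 2:
        raise ValueError("msd_curve needs at least 2 detections")
    dts = np.diff(trajectory.t)
    delta = float(np.median(dts))
    if delta > 0 and np.any(np.abs(dts - delta) > uniform_tol * delta):
        warnings.warn(
            f"trajectory {trajectory.traj_id}: non-uniform sampling; "
            "lags taken as multiples of the median interval",
            stacklevel=2,
        )
    n_lags = n - 1 if max_lags is None else min(max_lags, n - 1)
    xy = trajectory.xy
    msd = np.empty(n_lags)
    for lag in range(1, n_lags + 1):
        disp = xy[lag:] - xy[:-lag]
        msd[lag - 1] = np.mean(np.sum(disp * disp, axis=1))
    lags = delta * np.arange(1, n_lags + 1)
    return lags, msd


def instantaneous_diffusion(lags: np.ndarray, msd: np.ndarray) -> float:
    """Instantaneous diffusion coefficient D (µm²/s).

    Least-squares slope of MSD against lag over the first four points,
    divided by 4 (2D diffusion: MSD = 4Dτ). NaN if fewer than 4 points.
    """
    if len(msd) < 4:
        return float("nan")
    slope = np.polyfit(lags[:4], msd[:4], 1)[0]
    return float(slope / 4.0)


def msd_alpha(lags: np.ndarray, msd: np.ndarray) -> float:
    """Anomalous exponent: slope of log MSD vs log lag over the first 4 points.

    alpha < 1 indicates confined motion, ≈ 1 Brownian, ≈ 2 directed.
    NaN if fewer than 4 points or any of the first 4 MSD values is 0.
    """
    if len(msd) < 4 or np.any(msd[:4] <= 0):
        return float("nan")
    return float(np.polyfit(np.log(lags[:4]), np.log(msd[:4]), 1)[0])


def extract_segments(trajectory: Trajectory) -> list[Segment]:
    """Decompose a trajectory into its n_steps consecutive segments."""
    if trajectory.n_detections < 2:
        raise ValueError("extract_segments needs at least 2 detections")
    xy, t = trajectory.xy, trajectory.t
    return [
        Segment(
            trajectory.traj_id,
            i,
            float(xy[i, 0]),
            float(xy[i, 1]),
            float(t[i]),
            float(xy[i + 1, 0]),
            float(xy[i + 1, 1]),
            float(t[i + 1]),
        )
        for i in range(trajectory.n_detections - 1)
    ]


def compute_features(
    trajectory: Trajectory, max_lags: int | None = 10, radius_mode: str = "area"
) -> TrajFeatures:
    """All scalar features for one trajectory."""
    cx, cy, ct = trajectory.centroid()
    area, radius = hull_area_and_radius(trajectory, radius_mode=radius_mode)
    lags, msd = msd_curve(trajectory, max_lags=max_lags)
    return TrajFeatures(
        traj_id=trajectory.traj_id,
        centroid_x=cx,
        centroid_y=cy,
        centroid_t=ct,
        hull_area=area,
        approx_radius=radius,
        msd_lags=lags,
        msd=msd,
        d_inst=instantaneous_diffusion(lags, msd),
        alpha=msd_alpha(lags, msd),
        n_steps=trajectory.n_steps,
    )
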
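"""Reading and writing TRXYT trajectory data and regions of interest.

TRXYT is the four-column, header-less, space-separated trajectory exchange
format used by single-particle tracking pipelines: trajectory number,
x coordinate (µm), y coordinate (µm), detection time (s). Regions of
interest travel as tab-separated ``roi_coordinates.tsv`` files with one
polygon vertex per line (roi id, x, y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon


class TrxytParseError(ValueError):
    """A TRXYT or ROI file line could not be parsed."""


@dataclass(frozen=True)
class Detection:
    """A single localization: one molecule at one frame."""

    traj_id: int
    x: float
    y: float
    t: float


@dataclass
class Trajectory:
    """Time-ordered localizations of one tracked molecule.

    Coordinates are stored as an ``(n, 2)`` array in µm and times as an
    ``(n,)`` array in seconds, both sorted by time.
    """

    traj_id: int
    xy: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        if len(self.t) != len(self.xy):
            raise ValueError("xy and t length mismatch")
        if len(self.t) == 0:
            raise ValueError("trajectory needs at least one detection")
        if np.any(np.diff(self.t) < 0):
            warnings.warn(
                f"trajectory {self.traj_id}: non-monotone timestamps, sorting",
                stacklevel=2,
            )
            order = np.argsort(self.t, kind="stable")
            self.t = self.t[order]
            self.xy = self.xy[order]

    @property
    def n_detections(self) -> int:
        return len(self.t)

    @property
    def n_steps(self) -> int:
        """Number of displacement segments (detections − 1)."""
        return len(self.t) - 1

    @property
    def detections(self) -> list[Detection]:
        return [
            Detection(self.traj_id, float(x), float(y), float(tt))
            for (x, y), tt in zip(self.xy, self.t)
        ]

    def centroid(self) -> tuple[float, float, float]:
        """Unweighted spatiotemporal centroid (x, y, t)."""
        cx, cy = self.xy.mean(axis=0)
        return float(cx), float(cy), float(self.t.mean())


@dataclass
class ROI:
    """Simple polygonal region of interest in µm."""

    roi_id: int
    vertices: Sequence[tuple[float, float]] = field(default_factory=list)

    def polygon(self) -> Polygon:
        if len(self.vertices) < 3:
            raise ValueError(f"ROI {self.roi_id}: needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"ROI {self.roi_id}: polygon is not simple")
        if poly.area == 0:
            raise ValueError(f"ROI {self.roi_id}: degenerate (zero-area) polygon")
        return poly


def rectangle_roi(xmin: float, ymin: float, xmax: float, ymax: float, roi_id: int = 1) -> ROI:
    """Axis-aligned rectangular ROI convenience constructor."""
    return ROI(roi_id, [(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])


def read_trxyt(path: str | Path) -> list[Trajectory]:
    """Read a TRXYT file into time-sorted trajectories.

    Detections are grouped by trajectory number; ids are preserved from the
    file. Columns beyond the fourth are ignored. A malformed (non-numeric)
    field raises :class:`TrxytParseError` naming the line; an empty file
    returns an empty list with a warning.
    """
    path = Path(path)
    ids: list[int] = []
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise TrxytParseError(
                    f"{path.name}:{lineno}: expected >= 4 fields, got {len(parts)}"
                )
            try:
                tid = int(float(parts[0]))
                x, y, t = float(parts[1]), float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise TrxytParseError(
                    f"{path.name}:{lineno}: non-numeric field in {parts[:4]!r}"
                ) from exc
            ids.append(tid)
            rows.append((x, y, t))
    if not rows:
        warnings.warn(f"{path.name}: empty TRXYT file", stacklevel=2)
        return []
    ids_arr = np.array(ids)
    data = np.array(rows)
    trajectories = []
    # keep first-appearance order of ids, stable within each trajectory
    _, first_idx = np.unique(ids_arr, return_index=True)
    for tid in ids_arr[np.sort(first_idx)]:
        mask = ids_arr == tid
        trajectories.append(Trajectory(int(tid), data[mask, :2], data[mask, 2]))
    return trajectories


def write_trxyt(trajectories: Iterable[Trajectory], path: str | Path, decimals: int = 5) -> None:
    """Write trajectories as header-less four-column TRXYT."""
    with open(path, "w") as fh:
        for traj in trajectories:
            for (x, y), t in zip(traj.xy, traj.t):
                fh.write(f"{traj.traj_id} {x:.{decimals}f} {y:.{decimals}f} {t:.{decimals}f}\n")


def select_in_roi(trajectories: Sequence[Trajectory], roi: ROI) -> list[Trajectory]:
    """Keep trajectories whose spatial centroid lies in (or on) the ROI polygon.

    Trajectories are the indivisible unit of the analysis: they are kept
    whole or dropped whole, never split at the ROI boundary.
    """
    poly = roi.polygon()
    kept = []
    for traj in trajectories:
        cx, cy, _ = traj.centroid()
        if poly.covers(Point(cx, cy)):  # boundary counts as inside
            kept.append(traj)
    return kept


def filter_min_steps(trajectories: Sequence[Trajectory], min_steps: int = 8) -> list[Trajectory]:
    """Retain trajectories with at least ``min_steps`` displacement segments.

    "Steps" counts segments (detections − 1), the usual SPT convention; pass
    ``min_steps = n - 1`` to reproduce a detections-count convention instead.
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    return [traj for traj in trajectories if traj.n_steps >= min_steps]


def read_roi_tsv(path: str | Path) -> list[ROI]:
    """Read ``roi_coordinates.tsv`` (tab-separated: roi id, x, y; one vertex per line)."""
    path = Path(path)
    ids: list[int] = []
    verts: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) < 3:
                raise TrxytParseError(f"{path.name}:{lineno}: expected 3 tab-separated fields")
            try:
                ids.append(int(float(parts[0])))
                verts.append((float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise TrxytParseError(f"{path.name}:{lineno}: non-numeric coordinate") from exc
    rois: dict[int, list[tuple[float, float]]] = {}
    for rid, v in zip(ids, verts):
        rois.setdefault(rid, []).append(v)
    return [ROI(rid, vs) for rid, vs in rois.items()]


def write_roi_tsv(rois: Iterable[ROI], path: str | Path, decimals: int = 5) -> None:
    with open(path, "w") as fh:
        for roi in rois:
            for x, y in roi.vertices:
                fh.write(f"{roi.roi_id}\t{x:.{decimals}f}\t{y:.{decimals}f}\n")
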
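"""Spatiotemporal box-intersection index.

Axis-aligned 3D (x, y, t) boxes are binned into a uniform spatial grid;
candidate pairs sharing a grid cell are then checked with the exact
closed-interval intersection test in all three dimensions. Closed intervals
mean touching boxes count as overlapping. The exhaustive all-pairs test is
deliberately *not* used here — it lives in the test suite as the
independent oracle for this module.

Boxes are ``(n, 6)`` float arrays with columns
``x_lo, x_hi, y_lo, y_hi, t_lo, t_hi``.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

BOX_COLS = ("x_lo", "x_hi", "y_lo", "y_hi", "t_lo", "t_hi")


def _pairs_overlap(boxes: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Exact closed-interval intersection test for candidate index pairs."""
    b_i, b_j = boxes[i], boxes[j]
    ok = (
        (b_i[:, 0] <= b_j[:, 1])
        & (b_j[:, 0] <= b_i[:, 1])
        & (b_i[:, 2] <= b_j[:, 3])
        & (b_j[:, 2] <= b_i[:, 3])
        & (b_i[:, 4] <= b_j[:, 5])
        & (b_j[:, 4] <= b_i[:, 5])
    )
    return ok


def query_box_overlaps(boxes: np.ndarray) -> np.ndarray:
    """All intersecting box pairs, as an ``(m, 2)`` array of row indices i < j.

    Symmetric by construction (each unordered pair reported once), no
    self-pairs; intervals are closed in every dimension.
    """
    boxes = np.asarray(boxes, dtype=float)
    n = len(boxes)
    if n < 2:
        return np.empty((0, 2), dtype=int)

    # grid cell size from the median box footprint; fall back to full extent
    widths = np.concatenate([boxes[:, 1] - boxes[:, 0], boxes[:, 3] - boxes[:, 2]])
    cell = float(np.median(widths))
    if cell <= 0:
        cell = max(float(np.max(widths)), 1e-9)
    x0 = float(boxes[:, 0].min())
    y0 = float(boxes[:, 2].min())

    buckets: defaultdict[tuple[int, int], list[int]] = defaultdict(list)
    ix_lo = np.floor((boxes[:, 0] - x0) / cell).astype(int)
    ix_hi = np.floor((boxes[:, 1] - x0) / cell).astype(int)
    iy_lo = np.floor((boxes[:, 2] - y0) / cell).astype(int)
    iy_hi = np.floor((boxes[:, 3] - y0) / cell).astype(int)
    for k in range(n):
        for gx in range(ix_lo[k], ix_hi[k] + 1):
            for gy in range(iy_lo[k], iy_hi[k] + 1):
                buckets[(gx, gy)].append(k)

    cand_i: list[np.ndarray] = []
    cand_j: list[np.ndarray] = []
    for members in buckets.values():
        m = len(members)
        if m < 2:
            continue
        arr = np.array(members)
        ii, jj = np.triu_indices(m, k=1)
        cand_i.append(arr[ii])
        cand_j.append(arr[jj])
    if not cand_i:
        return np.empty((0, 2), dtype=int)
    i = np.concatenate(cand_i)
    j = np.concatenate(cand_j)
    # dedupe pairs seen in several shared cells
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    keys = np.unique(lo.astype(np.int64) * n + hi)
    i = (keys // n).astype(int)
    j = (keys % n).astype(int)
    ok = _pairs_overlap(boxes, i, j)
    return np.column_stack([i[ok], j[ok]])


def overlap_counts(boxes: np.ndarray, group: np.ndarray | None = None) -> np.ndarray:
    """Per-box count of intersecting boxes, optionally excluding same-group pairs.

    ``group`` (e.g. the parent trajectory id of each segment box) suppresses
    intra-group overlaps from the counts.
    """
    n = len(boxes)
    counts = np.zeros(n, dtype=int)
    pairs = query_box_overlaps(boxes)
    if len(pairs) == 0:
        return counts
    if group is not None:
        group = np.asarray(group)
        keep = group[pairs[:, 0]] != group[pairs[:, 1]]
        pairs = pairs[keep]
    np.add.at(counts, pairs[:, 0], 1)
    np.add.at(counts, pairs[:, 1], 1)
    return counts
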
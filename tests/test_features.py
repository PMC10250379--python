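"""Centroids, hulls, MSD curves, diffusion metrics and segments."""

import math

import numpy as np
import pytest

from conftest import brownian_trajectory
from nastic.features import (
    extract_segments,
    hull_area_and_radius,
    instantaneous_diffusion,
    msd_alpha,
    msd_curve,
    spatiotemporal_centroid,
)
from nastic.io import Trajectory


class TestCentroid:
    def test_two_point_mean(self):
        tr = Trajectory(1, [[0, 0], [2, 2]], [0, 10])
        assert spatiotemporal_centroid(tr) == (1, 1, 5)

    def test_single_detection_identity(self):
        tr = Trajectory(1, [[3.5, -1.0]], [7.0])
        assert spatiotemporal_centroid(tr) == (3.5, -1.0, 7.0)

    def test_typical_four_detections(self):
        # hand average of the canonical 4-line TRXYT excerpt
        xy = [[9.0117, 39.86], [8.9603, 39.837], [9.093, 39.958], [9.0645, 39.975]]
        tr = Trajectory(1, xy, [0.02, 0.04, 0.06, 0.08])
        cx, cy, ct = spatiotemporal_centroid(tr)
        assert cx == pytest.approx(9.032375)
        assert cy == pytest.approx(39.9075)
        assert ct == pytest.approx(0.05)


def _monotone_chain_area(points):
    """Independent convex-hull area oracle (Andrew's monotone chain + shoelace)."""
    pts = sorted(map(tuple, points))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestHull:
    def test_square(self):
        tr = Trajectory(1, [[0, 0], [2, 0], [2, 2], [0, 2]], [0, 1, 2, 3])
        area, radius = hull_area_and_radius(tr)
        assert area == pytest.approx(4.0)
        assert radius == pytest.approx(math.sqrt(4 / math.pi))

    def test_coincident_detections(self):
        tr = Trajectory(1, np.ones((5, 2)), np.arange(5.0))
        assert hull_area_and_radius(tr) == (0.0, 0.0)

    def test_collinear_fallback_half_max_distance(self):
        tr = Trajectory(1, [[0, 0], [1, 0], [3, 0]], [0, 1, 2])
        area, radius = hull_area_and_radius(tr)
        assert area == 0.0
        assert radius == pytest.approx(1.5)

    def test_random_cloud_matches_monotone_chain(self, rng):
        pts = rng.uniform(0, 5, size=(50, 2))
        tr = Trajectory(1, pts, np.arange(50.0))
        area, radius = hull_area_and_radius(tr)
        assert area == pytest.approx(_monotone_chain_area(pts), rel=1e-9)
        assert radius**2 * math.pi == pytest.approx(area)

    def test_maxdist_mode(self):
        tr = Trajectory(1, [[0, 0], [2, 0], [2, 2], [0, 2]], [0, 1, 2, 3])
        _, radius = hull_area_and_radius(tr, radius_mode="maxdist")
        assert radius == pytest.approx(math.sqrt(8) / 2)


def _brute_force_msd(xy, lag):
    vals = [np.sum((xy[i + lag] - xy[i]) ** 2) for i in range(len(xy) - lag)]
    return np.mean(vals)


class TestMsdCurve:
    def test_ballistic(self):
        n = 10
        xy = np.column_stack([0.1 * np.arange(n), np.zeros(n)])
        tr = Trajectory(1, xy, 0.02 * np.arange(n))
        lags, msd = msd_curve(tr)
        assert msd[0] == pytest.approx(0.01)
        for k, value in enumerate(msd, start=1):
            assert value == pytest.approx((0.1 * k) ** 2)

    def test_immobile_all_zero(self):
        tr = Trajectory(1, np.zeros((8, 2)), 0.02 * np.arange(8))
        _, msd = msd_curve(tr)
        np.testing.assert_array_equal(msd, 0.0)

    def test_matches_brute_force_on_random_walk(self, rng):
        tr = brownian_trajectory(rng, D=0.05, n=30)
        lags, msd = msd_curve(tr, max_lags=10)
        assert len(msd) == 10
        for k in range(1, 11):
            assert msd[k - 1] == pytest.approx(_brute_force_msd(tr.xy, k))

    def test_brownian_ensemble_recovers_diffusion(self, rng):
        D = 0.02
        slopes = []
        for i in range(1000):
            tr = brownian_trajectory(rng, D, n=30)
            lags, msd = msd_curve(tr, max_lags=4)
            slopes.append(instantaneous_diffusion(lags, msd))
        mean, sem = np.mean(slopes), np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - D) < 3 * sem

    def test_nonuniform_sampling_warns(self):
        tr = Trajectory(1, np.zeros((5, 2)), [0, 0.02, 0.04, 0.2, 0.22])
        with pytest.warns(UserWarning, match="non-uniform"):
            msd_curve(tr)


class TestDiffusionScalars:
    def test_exact_linear_msd(self):
        lags = 0.02 * np.arange(1, 6)
        msd = 4 * 0.01 * lags
        assert instantaneous_diffusion(lags, msd) == pytest.approx(0.01)

    def test_zero_msd(self):
        lags = 0.02 * np.arange(1, 5)
        assert instantaneous_diffusion(lags, np.zeros(4)) == pytest.approx(0.0)

    def test_too_few_points_flagged(self):
        lags = 0.02 * np.arange(1, 4)
        assert math.isnan(instantaneous_diffusion(lags, np.ones(3)))
        assert math.isnan(msd_alpha(lags, np.ones(3)))

    def test_noisy_linear_matches_ols_oracle(self, rng):
        lags = 0.02 * np.arange(1, 5)
        msd = 0.04 * lags + rng.normal(0, 1e-4, 4)
        x, y = lags - lags.mean(), msd - msd.mean()
        slope = float((x * y).sum() / (x * x).sum())
        assert instantaneous_diffusion(lags, msd) == pytest.approx(slope / 4, abs=1e-12)

    def test_alpha_ballistic_is_two(self):
        n = 10
        xy = np.column_stack([0.1 * np.arange(n), np.zeros(n)])
        tr = Trajectory(1, xy, 0.02 * np.arange(n))
        lags, msd = msd_curve(tr)
        assert msd_alpha(lags, msd) == pytest.approx(2.0, abs=1e-9)

    def test_alpha_of_power_laws(self):
        lags = 0.02 * np.arange(1, 8)
        assert msd_alpha(lags, 0.3 * lags) == pytest.approx(1.0, abs=1e-9)
        assert msd_alpha(lags, 0.3 * lags**0.5) == pytest.approx(0.5, abs=1e-9)

    def test_alpha_undefined_with_zero_msd(self):
        lags = 0.02 * np.arange(1, 5)
        assert math.isnan(msd_alpha(lags, np.array([0.0, 1, 1, 1])))


class TestSegments:
    def test_counts(self):
        tr4 = Trajectory(1, np.arange(8.0).reshape(4, 2), [0, 1, 2, 3])
        assert len(extract_segments(tr4)) == 3
        tr2 = Trajectory(1, np.arange(4.0).reshape(2, 2), [0, 1])
        assert len(extract_segments(tr2)) == 1

    def test_order_and_endpoints(self):
        tr = Trajectory(1, [[0, 0], [1, 2], [3, 3]], [0.0, 0.02, 0.04])
        segs = extract_segments(tr)
        assert (segs[0].x2, segs[0].y2) == (1, 2)
        assert (segs[1].x1, segs[1].y1) == (1, 2)
        assert segs[0].mid_time == pytest.approx(0.01)

    def test_total_over_dataset(self, random_trajectories):
        total = sum(len(extract_segments(t)) for t in random_trajectories)
        assert total == sum(t.n_detections - 1 for t in random_trajectories)
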
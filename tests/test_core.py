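"""Box construction, overlap queries, connected clusters and the pipeline."""

import math

import numpy as np
import pytest

from conftest import brownian_trajectory, brute_force_box_overlaps
from nastic._index import query_box_overlaps
from nastic.core import (
    Boxes,
    Cluster,
    ClusterParams,
    build_boxes,
    cluster_metrics,
    connected_clusters,
    msd_prefilter,
    query_overlaps,
    run_nastic,
    run_nastic2c,
    secondary_pass,
)
from nastic.features import TrajFeatures, compute_features
from nastic.io import Trajectory
from nastic.simulate import SimConfig, _confined_walk


def random_boxes(rng, n, side_scale=1.0, t_scale=50.0):
    centers = rng.uniform(0, 10, size=(n, 2))
    halves = rng.uniform(0.01, side_scale, size=n)
    t_lo = rng.uniform(0, 300, size=n)
    t_hi = t_lo + rng.uniform(0.1, t_scale, size=n)
    return np.column_stack(
        [
            centers[:, 0] - halves,
            centers[:, 0] + halves,
            centers[:, 1] - halves,
            centers[:, 1] + halves,
            t_lo,
            t_hi,
        ]
    )


class TestIndex:
    def test_touching_and_overlapping(self):
        bounds = np.array([[0, 1, 0, 1, 0, 1], [0.5, 1.5, 0.5, 1.5, 0.5, 1.5]])
        assert len(query_box_overlaps(bounds)) == 1
        touching = np.array([[0, 1, 0, 1, 0, 1], [1, 2, 0, 1, 0, 1]])
        assert len(query_box_overlaps(touching)) == 1  # closed intervals

    def test_temporal_separation(self):
        bounds = np.array([[0, 1, 0, 1, 0, 10], [0, 1, 0, 1, 200, 210]])
        assert len(query_box_overlaps(bounds)) == 0

    def test_matches_brute_force(self, rng):
        for trial in range(20):
            n = int(rng.integers(2, 120))
            bounds = random_boxes(rng, n)
            got = {tuple(p) for p in query_box_overlaps(bounds)}
            assert got == brute_force_box_overlaps(bounds)

    def test_matches_brute_force_degenerate_widths(self, rng):
        # zero-width boxes (points/segments) still obey closed-interval semantics
        bounds = random_boxes(rng, 80)
        bounds[::3, 1] = bounds[::3, 0]
        bounds[::4, 3] = bounds[::4, 2]
        got = {tuple(p) for p in query_box_overlaps(bounds)}
        assert got == brute_force_box_overlaps(bounds)


class TestBuildBoxes:
    def _feat(self, tid=1, x=0.0, y=0.0, t=50.0, radius=1.0):
        return TrajFeatures(tid, x, y, t, math.pi * radius**2, radius)

    def test_default_window_example(self):
        boxes = build_boxes([self._feat()], ClusterParams(1.2, 20.0))
        np.testing.assert_allclose(boxes.bounds[0], [-1.2, 1.2, -1.2, 1.2, 40, 60])

    def test_r_one_circumscribes_equivalent_circle(self):
        boxes = build_boxes([self._feat(radius=0.5)], ClusterParams(1.0, 10.0))
        x_lo, x_hi = boxes.bounds[0, :2]
        assert x_hi - x_lo == pytest.approx(1.0)

    def test_side_closed_form_random(self, rng):
        feats = [
            self._feat(tid=i, radius=float(rng.uniform(0.01, 2)))
            for i in range(100)
        ]
        params = ClusterParams(1.7, 20.0)
        boxes = build_boxes(feats, params)
        for f, row in zip(feats, boxes.bounds):
            assert row[1] - row[0] == pytest.approx(2 * 1.7 * math.sqrt(f.hull_area / math.pi))

    def test_zero_radius_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero approximate radius"):
            boxes = build_boxes([self._feat(radius=0.0)], ClusterParams())
        assert len(boxes.ids) == 0


class TestMsdPrefilter:
    def _feat_with_msd(self, tid, scalar):
        return TrajFeatures(tid, 0, 0, 0, 0, 1, np.array([1.0]), np.array([scalar]))

    def test_mean_threshold(self):
        feats = [self._feat_with_msd(i, s) for i, s in enumerate([1, 1, 1, 9])]
        kept, excluded = msd_prefilter(feats)
        assert [f.traj_id for f in kept] == [0, 1, 2]
        assert excluded == [3]

    def test_all_equal_retained(self):
        feats = [self._feat_with_msd(i, 2.0) for i in range(5)]
        kept, excluded = msd_prefilter(feats)
        assert len(kept) == 5 and excluded == []

    def test_slow_population_dominates_retained(self, rng):
        feats = []
        for i in range(500):
            tr = brownian_trajectory(rng, 0.001, n=20, traj_id=i)
            feats.append(compute_features(tr))
        for i in range(500, 1000):
            tr = brownian_trajectory(rng, 0.1, n=20, traj_id=i)
            feats.append(compute_features(tr))
        kept, _ = msd_prefilter(feats)
        slow = sum(1 for f in kept if f.traj_id < 500)
        assert slow / len(kept) > 0.95


def _union_find_components(n, pairs):
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for k in range(n):
        groups.setdefault(find(k), set()).add(k)
    return {frozenset(g) for g in groups.values()}


class TestConnectedClusters:
    def test_chain(self):
        adj = np.array([[1, 2], [2, 3], [3, 4]])
        clusters = connected_clusters(adj, [1, 2, 3, 4], ClusterParams())
        assert len(clusters) == 1
        assert sorted(clusters[0].member_traj_ids) == [1, 2, 3, 4]

    def test_isolated_pair_below_min_members(self):
        adj = np.array([[1, 2]])
        assert connected_clusters(adj, [1, 2, 3], ClusterParams(min_members=3)) == []

    def test_random_graphs_match_union_find(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 60))
            m = int(rng.integers(0, 3 * n))
            pairs = rng.integers(0, n, size=(m, 2))
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]
            ids = np.arange(100, 100 + n)
            clusters = connected_clusters(ids[pairs], ids, ClusterParams(min_members=2))
            got = {frozenset(c.member_traj_ids) for c in clusters}
            oracle = {
                frozenset(ids[list(g)])
                for g in _union_find_components(n, pairs.tolist())
                if len(g) >= 2
            }
            assert got == oracle


class TestClusterMetrics:
    def test_equilateral_triangle(self):
        side = 1.0
        pts = [(0, 0), (side, 0), (side / 2, side * math.sqrt(3) / 2)]
        trajs = {
            i + 1: Trajectory(i + 1, [p], [t])
            for i, (p, t) in enumerate(zip(pts, [5.0, 15.0, 25.0]))
        }
        feats = {i: compute_features_single(trajs[i]) for i in trajs}
        cl = cluster_metrics(Cluster(1, [1, 2, 3]), trajs, feats)
        assert cl.area == pytest.approx(math.sqrt(3) / 4)
        assert cl.lifetime == pytest.approx(20.0)
        assert cl.mean_time == pytest.approx(15.0)
        assert cl.radius == pytest.approx(math.sqrt(cl.area / math.pi))

    def test_simultaneous_detections_zero_lifetime(self):
        trajs = {
            1: Trajectory(1, [[0, 0]], [3.0]),
            2: Trajectory(2, [[1, 0]], [3.0]),
            3: Trajectory(3, [[0, 1]], [3.0]),
        }
        feats = {i: compute_features_single(trajs[i]) for i in trajs}
        cl = cluster_metrics(Cluster(1, [1, 2, 3]), trajs, feats)
        assert cl.lifetime == 0.0

    def test_radius_area_identity_on_run(self, rng):
        trajs, _ = _tiny_clustered_scene(rng)
        res = run_nastic(trajs, min_steps=0)
        assert res.clusters
        for cl in res.clusters:
            if cl.area > 0:
                assert cl.radius**2 * math.pi == pytest.approx(cl.area)


def compute_features_single(traj):
    """Features for possibly single-detection trajectories (metrics tests)."""
    cx, cy, ct = traj.centroid()
    return TrajFeatures(traj.traj_id, cx, cy, ct, 0.0, 0.0)


def _tiny_clustered_scene(rng, n_clusters=4, separation=2.0):
    cfg = SimConfig()
    trajs = []
    tid = 1
    for k in range(n_clusters):
        center = np.array([separation * k, 0.0])
        window = (40.0 * k, 40.0 * k + 10.0)
        for _ in range(5):
            trajs.append(_confined_walk(cfg, center, window, rng, tid))
            tid += 1
    truth = {tr.traj_id: (tr.traj_id - 1) // 5 for tr in trajs}
    return trajs, truth


class TestRunNastic:
    def test_empty_input(self):
        res = run_nastic([])
        assert res.clusters == [] and res.unclustered_ids == []

    def test_recovers_separated_clusters(self, rng):
        trajs, truth = _tiny_clustered_scene(rng)
        res = run_nastic(trajs, min_steps=0)
        assert len(res.clusters) == 4
        for cl in res.clusters:
            assert len({truth[t] for t in cl.member_traj_ids}) == 1

    def test_purely_spatial_at_double_acquisition(self, rng):
        cfg = SimConfig()
        trajs = []
        tid = 1
        for window in [(20.0, 30.0), (200.0, 210.0)]:  # co-located, separated in time
            for _ in range(5):
                trajs.append(_confined_walk(cfg, np.array([5.0, 5.0]), window, rng, tid))
                tid += 1
        split = run_nastic(trajs, ClusterParams(time_window=20), min_steps=0)
        merged = run_nastic(trajs, ClusterParams(time_window=640), min_steps=0)
        assert len(split.clusters) == 2
        assert len(merged.clusters) == 1

    def test_cluster_ids_ascend_with_mean_time(self, rng):
        trajs, _ = _tiny_clustered_scene(rng)
        res = run_nastic(trajs, min_steps=0)
        times = [c.mean_time for c in res.clusters]
        assert times == sorted(times)

    def test_deterministic_under_input_order(self, rng):
        trajs, _ = _tiny_clustered_scene(rng)
        res1 = run_nastic(trajs, min_steps=0)
        shuffled = [trajs[i] for i in rng.permutation(len(trajs))]
        res2 = run_nastic(shuffled, min_steps=0)
        parts1 = [c.member_traj_ids for c in res1.clusters]
        parts2 = [c.member_traj_ids for c in res2.clusters]
        assert parts1 == parts2

    def test_summary_counts_consistent(self, rng):
        trajs, _ = _tiny_clustered_scene(rng)
        res = run_nastic(trajs, min_steps=0)
        s = res.summary
        assert (
            s["clustered_trajectories"] + s["unclustered_trajectories"]
            == s["selected_trajectories"]
        )


class TestSecondaryPass:
    def test_time_window_is_double_acquisition(self, rng):
        trajs, _ = _tiny_clustered_scene(rng)
        res = secondary_pass(trajs, acquisition=320.0, min_steps=0)
        assert res.params.time_window == 640.0
        assert res.summary["pass"] == "secondary"

    def test_empty_input(self):
        res = secondary_pass([])
        assert res.clusters == []


class TestTwoColor:
    def _cluster_of(self, rng, center, window, n, tid0):
        cfg = SimConfig()
        return [
            _confined_walk(cfg, np.asarray(center), window, rng, tid0 + i)
            for i in range(n)
        ]

    def test_color_fractions(self, rng):
        c1 = self._cluster_of(rng, (0, 0), (10, 20), 3, 1)  # pure colour 1
        c1 += self._cluster_of(rng, (5, 5), (50, 60), 2, 10)  # mixed half
        c2 = self._cluster_of(rng, (5, 5), (50, 60), 2, 1)
        res = run_nastic2c(c1, c2, min_steps=0)
        fracs = sorted(cl.color_fraction for cl in res.clusters)
        assert fracs == [0.0, 0.5]

    def test_remapped_ids_disjoint(self, rng):
        c1 = self._cluster_of(rng, (0, 0), (10, 20), 3, 1)
        c2 = self._cluster_of(rng, (0, 0), (10, 20), 3, 1)  # same source ids
        res = run_nastic2c(c1, c2, min_steps=0)
        assert len(res.features) == 6
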
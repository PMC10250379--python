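"""Ground-truth synthetic trajectory generators.

Three scenarios emulate typical 50 Hz / 320 s single-particle tracking
acquisitions:

* ``gen_small_scenario`` — 50 free background trajectories in 4 µm² plus 20
  discrete clusters of 20 trajectories each, every cluster confined within a
  0.1 µm radius and a 10 s time window.
* ``gen_large_scenario`` — 100 spatially distinct cluster regions on a
  100 µm² membrane, 20% of which are hotspots holding 2–4 temporally
  separated clusters (expected 140 spatiotemporally unique clusters), each
  cluster 6–10 confined trajectories, over a background of 1000 free walks.
* ``gen_two_color_scenario`` — two large-scenario-style channels with
  shared cluster regions; the second molecule's steps are 10% longer.

Every trajectory is a random walk of 8–30 segments with step lengths drawn
Uniform(0, 0.1 µm) in an isotropic random direction at 20 ms intervals.
Confined trajectories are reflected at their cluster disc boundary so every
detection stays inside. Photophysics (blinking, localization error) and
mistracking are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Trajectory


@dataclass(frozen=True)
class SimConfig:
    area_side: float = 10.0  # µm (square ROI side; 100 µm² membrane)
    acquisition: float = 320.0  # s
    frame_interval: float = 0.02  # s (50 Hz)
    n_background: int = 1000
    n_regions: int = 100
    hotspot_fraction: float = 0.2
    clusters_per_hotspot: tuple[int, int] = (2, 4)
    trajs_per_cluster: tuple[int, int] = (6, 10)
    cluster_radius: float = 0.1  # µm confinement disc
    cluster_time_window: float = 10.0  # s
    hotspot_time_gap: float = 40.0  # s between windows in one hotspot
    steps_range: tuple[int, int] = (8, 30)
    max_step: float = 0.1  # µm; lengths ~ Uniform(0, max_step)
    min_region_spacing_factor: float = 4.0  # × cluster_radius
    seed: int = 0


@dataclass
class GroundTruthCluster:
    cluster_id: int
    center: tuple[float, float]
    t_window: tuple[float, float]
    hotspot_id: int | None
    member_traj_ids: list[int] = field(default_factory=list)
    color: int | None = None  # two-colour scenarios


@dataclass
class GroundTruth:
    labels: dict[int, int | None]  # traj_id -> cluster id or None
    clusters: list[GroundTruthCluster]
    config: SimConfig

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_clustered_trajectories(self) -> int:
        return sum(len(c.member_traj_ids) for c in self.clusters)

    @property
    def mean_members_per_cluster(self) -> float:
        return self.n_clustered_trajectories / self.n_clusters


def _reflect_into_disc(p: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect a point back inside the disc if a step leaves it."""
    d = float(np.hypot(*(p - center)))
    if d <= radius:
        return p
    # mirror the radial overshoot; valid while d <= 2*radius, guaranteed for
    # step lengths <= radius
    return center + (p - center) * (2 * radius - d) / d


def gen_random_walk(
    origin: np.ndarray,
    n_steps: int,
    max_step: float,
    frame_interval: float,
    t0: float,
    rng: np.random.Generator,
    confinement: tuple[np.ndarray, float] | None = None,
    traj_id: int = 1,
) -> Trajectory:
    """Isotropic random walk: step lengths Uniform(0, max_step), uniform
    directions; optional confinement disc with boundary reflection."""
    if not 1 <= n_steps <= 10_000:
        raise ValueError("n_steps out of range [1, 10000]")
    pts = np.empty((n_steps + 1, 2))
    pts[0] = origin
    lengths = rng.uniform(0.0, max_step, size=n_steps)
    angles = rng.uniform(0.0, 2 * np.pi, size=n_steps)
    steps = np.column_stack([lengths * np.cos(angles), lengths * np.sin(angles)])
    for i in range(n_steps):
        p = pts[i] + steps[i]
        if confinement is not None:
            p = _reflect_into_disc(p, confinement[0], confinement[1])
        pts[i + 1] = p
    t = t0 + frame_interval * np.arange(n_steps + 1)
    return Trajectory(traj_id, pts, t)


def _free_walk(cfg: SimConfig, rng: np.random.Generator, traj_id: int) -> Trajectory:
    n_steps = int(rng.integers(cfg.steps_range[0], cfg.steps_range[1] + 1))
    origin = rng.uniform(0.0, cfg.area_side, size=2)
    duration = n_steps * cfg.frame_interval
    t0 = rng.uniform(0.0, max(cfg.acquisition - duration, 0.0))
    return gen_random_walk(
        origin, n_steps, cfg.max_step, cfg.frame_interval, t0, rng, traj_id=traj_id
    )


def _confined_walk(
    cfg: SimConfig,
    center: np.ndarray,
    window: tuple[float, float],
    rng: np.random.Generator,
    traj_id: int,
    max_step: float | None = None,
) -> Trajectory:
    n_steps = int(rng.integers(cfg.steps_range[0], cfg.steps_range[1] + 1))
    # origin uniform in the confinement disc
    rad = cfg.cluster_radius * np.sqrt(rng.uniform())
    ang = rng.uniform(0.0, 2 * np.pi)
    origin = center + rad * np.array([np.cos(ang), np.sin(ang)])
    t0 = rng.uniform(window[0], window[1])
    return gen_random_walk(
        origin,
        n_steps,
        max_step if max_step is not None else cfg.max_step,
        cfg.frame_interval,
        t0,
        rng,
        confinement=(center, cfg.cluster_radius),
        traj_id=traj_id,
    )


def _spaced_centers(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Region centres uniform on the membrane with a minimum spacing."""
    min_d = cfg.min_region_spacing_factor * cfg.cluster_radius
    margin = cfg.cluster_radius
    if min_d <= 0:
        return rng.uniform(margin, cfg.area_side - margin, size=(n, 2))
    centers: list[np.ndarray] = []
    for _ in range(200_000):
        if len(centers) == n:
            break
        c = rng.uniform(margin, cfg.area_side - margin, size=2)
        if all(np.hypot(*(c - other)) >= min_d for other in centers):
            centers.append(c)
    else:
        raise RuntimeError(
            "could not place spatially distinct regions; increase area_side"
        )
    return np.array(centers)


def _separated_windows(
    cfg: SimConfig, k: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """k cluster time windows of cluster_time_window s whose starts are
    separated by at least window + hotspot_time_gap, uniform given the
    constraint (order-statistics construction)."""
    gap = cfg.cluster_time_window + cfg.hotspot_time_gap
    span = cfg.acquisition - cfg.cluster_time_window - gap * (k - 1)
    if span < 0:
        raise ValueError("acquisition too short for requested hotspot windows")
    starts = np.sort(rng.uniform(0.0, span, size=k)) + gap * np.arange(k)
    return [(float(s), float(s + cfg.cluster_time_window)) for s in starts]


def gen_small_scenario(seed: int = 0) -> tuple[list[Trajectory], GroundTruth]:
    """50 free trajectories in 4 µm² over 0–320 s plus 20 clusters of 20
    confined trajectories each (450 trajectories total).

    Clusters are interspersed without a spacing constraint, so the dataset
    exhibits all four cluster classes: discrete in space and time, spatially
    overlapping but temporally resolved, partially overlapping, and fully
    overlapping.
    """
    cfg = SimConfig(
        area_side=2.0,
        n_background=50,
        n_regions=20,
        hotspot_fraction=0.0,
        trajs_per_cluster=(20, 20),
        min_region_spacing_factor=0.0,
        seed=seed,
    )
    return _generate(cfg)


def gen_large_scenario(seed: int = 0, config: SimConfig | None = None) -> tuple[list[Trajectory], GroundTruth]:
    """The large hotspot scenario: 100 regions on 100 µm², 20% hotspots of
    2–4 temporally separated clusters (expected 140 clusters of ~8
    trajectories), 1000 background free walks, 320 s."""
    cfg = replace(config or SimConfig(), seed=seed)
    return _generate(cfg)


def _generate(cfg: SimConfig) -> tuple[list[Trajectory], GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    centers = _spaced_centers(cfg, cfg.n_regions, rng)
    n_hotspots = int(round(cfg.hotspot_fraction * cfg.n_regions))
    hotspot_regions = set(rng.choice(cfg.n_regions, size=n_hotspots, replace=False).tolist())

    trajectories: list[Trajectory] = []
    labels: dict[int, int | None] = {}
    gt_clusters: list[GroundTruthCluster] = []
    next_traj = 1
    next_cluster = 1
    for region in range(cfg.n_regions):
        center = centers[region]
        if region in hotspot_regions:
            k = int(rng.integers(cfg.clusters_per_hotspot[0], cfg.clusters_per_hotspot[1] + 1))
            windows = _separated_windows(cfg, k, rng)
            hotspot_id = region
        else:
            start = rng.uniform(0.0, cfg.acquisition - cfg.cluster_time_window)
            windows = [(start, start + cfg.cluster_time_window)]
            hotspot_id = None
        for window in windows:
            n_members = int(
                rng.integers(cfg.trajs_per_cluster[0], cfg.trajs_per_cluster[1] + 1)
            )
            gtc = GroundTruthCluster(next_cluster, tuple(center), window, hotspot_id)
            for _ in range(n_members):
                traj = _confined_walk(cfg, center, window, rng, next_traj)
                trajectories.append(traj)
                labels[next_traj] = next_cluster
                gtc.member_traj_ids.append(next_traj)
                next_traj += 1
            gt_clusters.append(gtc)
            next_cluster += 1
    for _ in range(cfg.n_background):
        trajectories.append(_free_walk(cfg, rng, next_traj))
        labels[next_traj] = None
        next_traj += 1
    return trajectories, GroundTruth(labels, gt_clusters, cfg)


def gen_two_color_scenario(
    seed: int = 0,
    shared_fraction: float = 0.3,
    cross_time_fraction: float = 0.2,
    config: SimConfig | None = None,
) -> tuple[list[Trajectory], list[Trajectory], GroundTruth]:
    """Two channels sharing seed regions.

    ``shared_fraction`` of regions hold mixed clusters (both colours in the
    same disc and window); ``cross_time_fraction`` hold one cluster of each
    colour at the same centre but temporally separated windows (cross-colour
    hotspots); the rest are colour-exclusive, alternating. Molecule 2 steps
    are 10% longer. Returns (colour-1 trajectories, colour-2 trajectories,
    combined ground truth with per-cluster colour: 0 = both, 1, or 2).
    """
    cfg = replace(config or SimConfig(n_regions=60, n_background=400), seed=seed)
    rng = np.random.default_rng(cfg.seed)
    centers = _spaced_centers(cfg, cfg.n_regions, rng)
    n_shared = int(round(shared_fraction * cfg.n_regions))
    n_cross = int(round(cross_time_fraction * cfg.n_regions))
    step2 = 1.1 * cfg.max_step

    t1: list[Trajectory] = []
    t2: list[Trajectory] = []
    labels: dict[int, int | None] = {}
    gt_clusters: list[GroundTruthCluster] = []
    next_traj = 1
    next_cluster = 1

    def add_cluster(center, window, colors, hotspot_id=None):
        nonlocal next_traj, next_cluster
        n_members = int(rng.integers(cfg.trajs_per_cluster[0], cfg.trajs_per_cluster[1] + 1))
        n_members = max(n_members, 2 * len(colors))  # >= 2 per colour in mixed
        color_tag = 0 if len(colors) == 2 else colors[0]
        gtc = GroundTruthCluster(next_cluster, tuple(center), window, hotspot_id, color=color_tag)
        for m in range(n_members):
            color = colors[m % len(colors)]
            traj = _confined_walk(
                cfg, center, window, rng, next_traj,
                max_step=step2 if color == 2 else cfg.max_step,
            )
            (t1 if color == 1 else t2).append(traj)
            labels[next_traj] = next_cluster
            gtc.member_traj_ids.append(next_traj)
            next_traj += 1
        gt_clusters.append(gtc)
        next_cluster += 1

    for region in range(cfg.n_regions):
        center = centers[region]
        if region < n_shared:
            start = rng.uniform(0.0, cfg.acquisition - cfg.cluster_time_window)
            add_cluster(center, (start, start + cfg.cluster_time_window), (1, 2))
        elif region < n_shared + n_cross:
            w1, w2 = _separated_windows(cfg, 2, rng)
            add_cluster(center, w1, (1,), hotspot_id=region)
            add_cluster(center, w2, (2,), hotspot_id=region)
        else:
            color = 1 if region % 2 == 0 else 2
            start = rng.uniform(0.0, cfg.acquisition - cfg.cluster_time_window)
            add_cluster(center, (start, start + cfg.cluster_time_window), (color,))

    for _ in range(cfg.n_background):
        for color, bucket in ((1, t1), (2, t2)):
            n_steps = int(rng.integers(cfg.steps_range[0], cfg.steps_range[1] + 1))
            origin = rng.uniform(0.0, cfg.area_side, size=2)
            t0 = rng.uniform(0.0, cfg.acquisition - n_steps * cfg.frame_interval)
            bucket.append(
                gen_random_walk(
                    origin, n_steps, step2 if color == 2 else cfg.max_step,
                    cfg.frame_interval, t0, rng, traj_id=next_traj,
                )
            )
            labels[next_traj] = None
            next_traj += 1
    return t1, t2, GroundTruth(labels, gt_clusters, cfg)


def gen_density_sweep(
    seed: int, multipliers: list[int], config: SimConfig | None = None
) -> list[tuple[list[Trajectory], GroundTruth]]:
    """Same clustered content, background scaled by each multiplier.

    The clustered portion is generated first from the seed so it is
    bit-identical across multipliers; extra background walks are appended
    from the continuation of the same stream.
    """
    if any(m < 1 for m in multipliers):
        raise ValueError("multipliers must be >= 1")
    base_cfg = replace(config or SimConfig(), seed=seed)
    out = []
    for mult in multipliers:
        cfg = replace(base_cfg, n_background=base_cfg.n_background * mult)
        out.append(_generate(cfg))
    return out


def write_ground_truth_tsv(gt: GroundTruth, path) -> None:
    """traj_id, cluster_id (blank = unclustered), hotspot_id (blank = none)."""
    hotspot_of = {c.cluster_id: c.hotspot_id for c in gt.clusters}
    with open(path, "w") as fh:
        fh.write("traj_id\tcluster_id\thotspot_id\n")
        for tid in sorted(gt.labels):
            cid = gt.labels[tid]
            hs = hotspot_of.get(cid) if cid is not None else None
            fh.write(
                f"{tid}\t{'' if cid is None else cid}\t{'' if hs is None else hs}\n"
            )
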
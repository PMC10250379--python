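import numpy as np
import pytest

from nastic.io import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(rng, traj_id=1, n=10, scale=1.0, origin=(0.0, 0.0), t0=0.0, dt=0.02):
    """Random trajectory with normal steps (helper, not a walk model claim)."""
    steps = rng.normal(scale=scale, size=(n - 1, 2))
    xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]) + np.asarray(origin)
    t = t0 + dt * np.arange(n)
    return Trajectory(traj_id, xy, t)


def brownian_trajectory(rng, D, n=50, dt=0.02, traj_id=1, origin=(0.0, 0.0), t0=0.0):
    """2D Brownian motion with diffusion coefficient D (µm²/s)."""
    steps = rng.normal(scale=np.sqrt(2 * D * dt), size=(n - 1, 2))
    xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]) + np.asarray(origin)
    return Trajectory(traj_id, xy, t0 + dt * np.arange(n))


@pytest.fixture
def random_trajectories(rng):
    return [
        make_trajectory(rng, traj_id=i + 1, n=int(rng.integers(2, 30)), scale=0.05,
                        origin=rng.uniform(0, 10, 2), t0=rng.uniform(0, 300))
        for i in range(100)
    ]


def brute_force_box_overlaps(bounds):
    """Exhaustive O(n²) closed-interval intersection oracle."""
    pairs = []
    n = len(bounds)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = bounds[i], bounds[j]
            if (
                a[0] <= b[1] and b[0] <= a[1]
                and a[2] <= b[3] and b[2] <= a[3]
                and a[4] <= b[5] and b[4] <= a[5]
            ):
                pairs.append((i, j))
    return set(pairs)
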
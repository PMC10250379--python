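"""Hotspots: recurrent clustering at the same membrane site, versus chance.

Clusters of clusters are found by grouping cluster centroids within
eps = 0.5 × mean cluster radius. A Monte Carlo null (same number of
centroids scattered uniformly over the same area, N = 50 replicates) shows
how much overlap randomness alone would produce.
"""

import numpy as np

from nastic import gen_large_scenario, run_nastic
from nastic.hotspots import (
    cluster_rate_timeline,
    detect_hotspots,
    hotspot_metrics,
    monte_carlo_null,
    overlap_probability_curve,
)

trajectories, _ = gen_large_scenario(seed=1)
result = run_nastic(trajectories)
clusters = result.clusters

mean_radius = float(np.mean([c.radius for c in clusters]))
eps = 0.5 * mean_radius
hotspots = detect_hotspots(clusters, eps=eps)
membership, intertime = hotspot_metrics(hotspots)
print(f"{len(clusters)} clusters, mean radius {1e3 * mean_radius:.1f} nm")
print(f"{len(hotspots)} hotspots at eps = {1e3 * eps:.1f} nm; "
      f"mean membership {membership:.2f} clusters, "
      f"mean intercluster time {intertime:.1f} s")

grid = np.array([eps])
(_, observed), = overlap_probability_curve(clusters, grid)
null_mean, null_sem = monte_carlo_null(len(clusters), 100.0, grid, seed=0)
print(f"overlap probability at eps: observed {observed:.3f} vs "
      f"random {null_mean[0]:.3f} ± {null_sem[0]:.3f}")
# observed >> null: the recurrence is built into the data (20% of regions
# hold 2-4 temporally separated clusters), not a sampling artefact.

traj_map = {tr.traj_id: tr for tr in trajectories}
_, rate = cluster_rate_timeline(clusters, traj_map, acquisition=320.0, roi_area=100.0)
print(f"cluster presence rate: {rate.mean():.4f} clusters/µm² per 1 s bin "
      f"(peak {rate.max():.4f})")
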
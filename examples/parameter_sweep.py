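"""How the two parameters (r, t) trade off against the ground truth.

For each (r, t) pair the clusterer is re-run and four metrics — clustered
trajectories, cluster count, members per cluster, cluster radius — are
compared with ground truth as log2(observed/GT), alongside ARI and IoU
label agreement. Values near 0 (log2) and 1 (ARI/IoU) are good.
"""

import numpy as np

from nastic import gen_large_scenario
from nastic.core import parameter_sweep

trajectories, truth = gen_large_scenario(seed=1)
sweep = parameter_sweep(
    trajectories,
    truth.labels,
    r_grid=[0.6, 1.0, 1.2, 2.0],
    t_grid=[5, 20, 80, 640],
)

score = sweep.mean_abs_log2()
print("mean |log2(observed/GT)| over the four metrics (rows r, cols t):")
print("        " + "".join(f"t={t:<7g}" for t in sweep.t_grid))
for i, r in enumerate(sweep.r_grid):
    row = "".join(f"{v:<9.2f}" if np.isfinite(v) else "inf      " for v in score[i])
    print(f"r={r:<5g} {row}")
print("\nARI (label agreement):")
for i, r in enumerate(sweep.r_grid):
    print(f"r={r:<5g} " + "".join(f"{v:<9.2f}" for v in sweep.ari[i]))
r_star, t_star = sweep.find_inflection()
print(f"\nbest-agreement grid point: r = {r_star}, t = {t_star} s")
# Large t merges temporally distinct clusters (purely spatial clustering at
# t = 2 x acquisition); large r bridges clusters through background walks.
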
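# nastic

**Nanoscale spatiotemporal indexing clustering of single-molecule
trajectories.**

Live-cell single-molecule localization microscopy (sptPALM, uPAINT) yields
thousands of short molecular trajectories on the plasma membrane. Membrane
proteins such as SNAREs transiently assemble into nanoclusters, and the
*temporal* structure of that clustering — apparent lifetimes, formation
rates, recurrent "hotspots" at the same membrane site — is invisible to
purely spatial cluster analyses (DBSCAN, Voronoï tessellation). This
package is for microscopists and analysts who need spatiotemporally
resolved nanocluster metrics from trajectory data.

## The algorithm

The trajectory, not the detection, is the indivisible unit. Each trajectory
is reduced to a 3D axis-aligned bounding box:

- spatial: a square centred on the trajectory's spatial centroid with
  half-side `r · ρ`, where `ρ = √(A/π)` is the area-equivalent
  ("approximate") radius of its convex hull of area `A`, and `r` is the
  bounding-box radius factor (default **r = 1.2**);
- temporal: the interval `[t̄ − t/2, t̄ + t/2]` around the temporal centroid
  `t̄`, where `t` is the time window (default **t = 20 s**).

Boxes are indexed and queried for pairwise intersection (closed intervals
in x, y and t); the connected components of the overlap graph with ≥ 3
member trajectories are the spatiotemporal clusters. Each cluster's extent
is the convex hull of all member detections, its radius `√(area/π)`, its
apparent lifetime the span of member detection times. Because the time
interval is part of the box, co-located clusters occurring at different
times are resolved natively; setting `t` to twice the acquisition recovers
purely spatial clustering.

Variants and companions, all in the library:

- **segment-level clustering** (`run_segnastic`): one box per displacement
  segment, thresholded at the mean other-trajectory overlap count — tighter
  hulls for dense data;
- **two-colour clustering** (`run_nastic2c`): joint clustering of two
  channels with per-cluster colour composition;
- **hotspots**: clusters-of-clusters within `0.5 ×` mean cluster radius,
  with overlap-probability curves against a Monte Carlo null;
- **confinement validation**: per-trajectory MSD alpha, hull area and
  VAR(1) coefficient/covariance norms, split by K-means into
  confined/unconfined and cross-tabulated against cluster membership;
- **baselines** (DBSCAN, Voronoï) and ARI/IoU label scoring;
- **synthetic data** with exact ground truth for all of the above.

## Worked example

```python
from nastic import gen_large_scenario, run_nastic
from nastic.baselines import score_labels

trajectories, truth = gen_large_scenario(seed=1)   # ~140 true clusters
result = run_nastic(trajectories)                  # r = 1.2, t = 20 s
score = score_labels(result.labels(), truth.labels)
```

Running `python examples/cluster_synthetic.py` (this scenario) prints:

```
ground truth: 136 clusters, 1070 clustered trajectories
recovered:    153 clusters, 1178 clustered trajectories
members/cluster 7.70 ± 0.18, radius 125.5 ± 4.0 nm, lifetime 11.8 s
hotspots: 20 holding 55 clusters (35.9%)
agreement with ground truth: ARI = 0.857, mean best-match IoU = 0.956
```

Every ground-truth cluster is recovered intact (hence IoU ≈ 0.96); the
extra ~17 clusters are chance triple-overlaps among the 1000 background
trajectories. The other example scripts exercise segment-level clustering,
two-colour composition, hotspot statistics against the Monte Carlo null,
VAR confinement validation and the (r, t) parameter sweep — each prints
its numbers with a line on what they mean.

## Command line

A thin CLI wraps the library for shell use:

```sh
nastic simulate --scenario large --seed 1 --out simdata
nastic run --trxyt simdata/trajectories.trxyt --r 1.2 --t 20 --out metrics.tsv
nastic seg --trxyt simdata/trajectories.trxyt
nastic hotspots --trxyt simdata/trajectories.trxyt --eps-frac 0.5
nastic wrangle condition_a/ condition_b/   # t-tests across metrics.tsv files
```

Input is the four-column TRXYT trajectory format (trajectory id, x µm,
y µm, t s; header-less, space-separated); regions of interest travel as
tab-separated `roi_coordinates.tsv` files.

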
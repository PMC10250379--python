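# Methods

## Spatiotemporal indexing clustering

Every trajectory with at least `min_steps` displacement segments (default
8; "steps" counts segments, i.e. detections − 1) is summarised by its
spatiotemporal centroid (unweighted mean of detection x, y, t), the area
`A` of the 2D convex hull of its detections, and the area-equivalent
radius `ρ = √(A/π)`. The hull's bounding square only captures the full
trajectory extent when the hull is circular, so the square box is scaled by
the radius factor `r > 1`; its half-side is `r·ρ`, centred on the spatial
centroid. The box is extruded in time to `t̄ ± t/2` around the temporal
centroid: with the default `t = 20 s`, each trajectory can pair with
others whose boxes reach within 10 s of its own centroid on either side.

Two boxes overlap when their intervals intersect in x, y **and** t, with
closed intervals — touching counts. Clusters are the connected components
of the overlap graph with at least `min_members = 3` trajectories ("three
or more proximal centroids"); every trajectory is in exactly one cluster or
unclustered. Cluster extent is the convex hull of all member detections;
radius `√(area/π)`; apparent lifetime the max − min member detection time;
cluster mean time the mean of member temporal centroids, which also orders
cluster ids, making the partition deterministic under input permutation.

Assumptions: 2D membrane data in µm/s; approximately uniform frame
intervals (non-uniform sampling triggers a warning and lags are taken as
multiples of the median interval); trajectories are indivisible — a
trajectory is clustered whole or not at all.

### The box index

Boxes are binned into a uniform spatial grid with cell size equal to the
median box footprint; pairs sharing a cell are checked with the exact
interval test. This is an ordinary spatial-hash index, adequate for the
10³–10⁵ boxes typical here; the test suite holds it to exact agreement
with the exhaustive O(n²) pairwise test on every instance tried (up to
2000 boxes / 5000 segment boxes).

### MSD pre-filter

The per-trajectory MSD scalar is the mean of the first four points of the
time-averaged MSD curve — the same window as the instantaneous diffusion
coefficient (slope of the first four MSD points / 4). When enabled,
trajectories with scalar above the population mean are withheld from the
index and reported unclustered. The filter is off by default: it exists to
keep high background densities from bridging clusters, and at ordinary
densities it would only discard mobile trajectories needlessly.

### Secondary pass and two-colour analysis

The secondary pass re-clusters primary-unclustered trajectories with
`t = 2 × acquisition` (inferred as the detection-time span unless given),
i.e. purely spatial clustering of loosely interacting molecules. Two-colour
analysis re-maps both channels onto disjoint id ranges, clusters the union
jointly, and annotates each cluster with the fraction of members from
channel 2.

### Segment-level clustering

Each displacement segment gets a box spanning its endpoints' x/y extent
(zero-width extents kept; closed intervals make them well defined) and a
time interval of `t` centred on the segment's mid-time. Per segment, the
number of overlapping boxes belonging to *other* trajectories is counted;
the candidate threshold is the arithmetic mean of these counts — the
histogram of overlap counts is heavily right-skewed, and its inflection
sits at the mean. The comparison is strict (ties at the mean are
non-candidates). Above-threshold segments are clustered by box overlap;
a segment cluster is accepted when its segments come from ≥ 3 distinct
parent trajectories, mirroring the trajectory-level rule, which the
source procedure leaves unstated at segment level.

## Hotspots

A hotspot is ≥ 2 clusters whose centroids lie within `eps` of each other,
default `eps = 0.5 ×` mean cluster radius. With MinPts = 2, density
clustering of centroids reduces exactly to connected components of the
≤ eps distance graph, and it is implemented as such (the equivalence with
DBSCAN is asserted in tests). Overlap probability at eps is
`1 − (centroids with no neighbour within eps)/total`; the Monte Carlo null
scatters the same number of centroids uniformly over the analysis area
(N = 50 replicates, seeded) and reports mean ± SEM per eps. The Poisson
nearest-neighbour closed form `1 − exp(−λπε²(n−1)/n)` serves as an
approximate analytic check; it ignores edge effects, so agreement is
expected only to within a small bias at eps approaching the box side.
Intercluster time averages the successive gaps between time-sorted member
cluster mean-times. The cluster-rate timeline counts clusters whose
detection span intersects each 1 s bin, per µm².

## Confinement validation

Per trajectory (≥ 6 detections): MSD alpha (log-log slope of the first
four MSD points), hull area, and the Frobenius norms of the VAR(1)
coefficient matrix `A` and residual covariance from least-squares fitting
`p_i = A·p_{i−1} + e_i` on the per-trajectory mean-centred positions —
positions, not increments, since the question is whether each position
depends on the previous one. Minimum-norm least squares tolerates
collinear designs (pure drift); only zero-variance (immobile) trajectories
are rejected and reported. K-means (k = 2, 10 restarts, fixed seed) runs
on z-scored features — without standardization the µm²-scale hull area
dominates — and the group with the smaller mean hull area is labelled
confined, hull area being the most direct confinement proxy of the four.
The Frobenius norm was chosen over the spectral norm; for these 2×2
matrices the two are within a factor √2 and the grouping is insensitive to
the choice.

## Temporal-uniformity statistics

Candidate hotspot locations are local maxima (strictly greater than all 8
neighbours) of a Gaussian KDE of trajectory spatial centroids, evaluated
on a 0.05 µm grid with Scott's-rule bandwidth; an optional prominence
factor suppresses the shallow maxima of uniform scatter. Each maximum
collects the trajectories whose centroid lies within 0.2 µm into a
temporal column; columns with fewer than 7 members are dropped. Member
*temporal centroids* (not raw detection times) are tested against
Uniform(acquisition span) by a one-sample Kolmogorov–Smirnov test; a
column is significant when `p < FWER/m` with FWER = 1% and m the number of
columns (Bonferroni). The uniform support is the full acquisition, not the
column's own span — the null hypothesis is "arrivals at this site are
unstructured over the experiment". Note the KS test's power profile: a
single burst near the middle of the acquisition, or several bursts spread
roughly evenly, can closely track the uniform CDF and escape detection;
this is a property of the statistic, not of the implementation.

## Baselines and scoring

DBSCAN runs on trajectory centroids (scikit-learn), with clusters smaller
than 3 demoted to noise. Voronoï clustering thresholds bounded tile areas
(unbounded boundary tiles are never clustered) and groups candidate tiles
that share a ridge — an edge, not merely a vertex — into components of
≥ 3. ARI treats all unclustered trajectories as one shared noise class;
mean IoU is the one-directional best Jaccard match per true cluster.

## Synthetic data

The generator emulates a 50 Hz, 320 s acquisition. Every trajectory is an
isotropic random walk of 8–30 segments at 20 ms intervals with step length
drawn Uniform(0, 0.1 µm) — the source only bounds the step below 0.1 µm,
and the uniform draw is the simplest consistent choice. Clustered
trajectories are confined to a 0.1 µm-radius disc by radial boundary
reflection (valid because steps never exceed the disc radius); their start
times fall inside the cluster's 10 s window. Background trajectories use
the same walk model, unconfined, uniform in space and time — the source
does not state the background step statistics.

Scenarios:

- **small**: 50 background walks in 4 µm² plus 20 clusters × 20
  trajectories, no spacing constraint (clusters may overlap in space
  and/or time, exhibiting all four cluster classes);
- **large**: 100 regions uniform on 10 × 10 µm with minimum spacing 4 ×
  cluster radius (keeping regions spatially distinct); 20% are hotspots
  with Uniform{2,3,4} clusters whose windows are drawn uniformly subject
  to ≥ 40 s separation (order-statistics construction, so clusters remain
  resolvable at t = 20 s); each cluster Uniform{6..10} members; 1000
  background walks. Expected composition: 140 clusters of 8 trajectories
  (1120 clustered) — the realised per-seed values scatter around these;
- **two-colour**: two channels; molecule 2's maximum step is 1.1 ×
  molecule 1's (10% longer segments on average); 30% of regions hold mixed
  clusters, 20% cross-colour hotspots (same centre, separated windows),
  the rest alternate colour-exclusively;
- **density sweep**: background count scaled by integer multipliers with
  the clustered content bit-identical across multipliers.

What the generator does *not* model: localization error, blinking and
gap-closing, mistracking, anisotropic or state-switching motion, spatially
varying background density. Passing tests therefore demonstrate algorithmic
correctness and behaviour under idealised confinement/background contrast,
not robustness to tracking artefacts in real acquisitions.

## Numerical choices and degenerate inputs

- Degenerate hulls (< 3 non-collinear detections): area 0, radius falls
  back to half the maximum pairwise distance so the trajectory still gets
  a box; single detections have radius 0 and are excluded from the index
  with a warning. A `radius_mode="maxdist"` switch replaces the
  area-equivalent radius throughout.
- Overlap queries use closed intervals; the conservative convention, and
  the one the exhaustive oracle implements.
- Cluster ids, hotspot member order and column ids are all sorted by time,
  so equal inputs give byte-equal outputs.
- Zero-variance time vectors in the KS test get the smallest positive
  float as p-value rather than 0.
- log2(observed/GT) with zero observed is recorded as −inf, and treated as
  an infinite penalty when locating the best-agreement grid point (ties
  broken by higher ARI, then smaller r and t).
- Condition comparison uses Student's (equal-variance) two-tailed t-test
  by default, Welch behind a flag; both pooled-cluster and per-file
  averaged modes are emitted.

## Problem sizes

The bundled scenarios are sized for interactive use: the large scenario
(~2100 trajectories, ~39000 segments) generates in ~0.3 s and clusters in
~1 s; the parameter sweep re-uses trajectory features across the grid. The
acceptance script averages ground-truth composition over 20 replicate
seeds and completes in a few seconds.

## Known limitations

- Spurious clusters from chance background overlaps (~10% of the cluster
  count at the large scenario's background density) are intrinsic to
  box-overlap clustering without the MSD pre-filter; they depress the
  cluster-count accuracy while leaving per-trajectory agreement (ARI/IoU)
  high.
- The KS-based hotspot test has little power against multi-burst arrival
  patterns spread evenly over the acquisition (see above).
- Voronoï clustering rejects all-collinear centroid sets (degenerate
  tessellation) rather than attempting a 1D fallback.
- The VAR fit is first-order only; no order selection is attempted.
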
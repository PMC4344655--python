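# Methods

## Problem and scope

The package partitions a marine study region into biophysical classes from
six per-pixel climatological variables: long-term mean sea-surface
temperature (Avg SST, °C), the maximum and minimum of the per-calendar-month
SST climatology (Max/Min SST, °C), long-term mean chlorophyll *a*
(mg m⁻³), long-term mean current speed (m s⁻¹) and long-term mean salinity
(PSU). The fixed study box is 113–135°E, 0–13°S (the Sunda Banda Seascape
in the central Coral Triangle), on a plate-carrée grid with cell-center
registration and north-to-south row order. Real satellite/model inputs
(4-km level-3 mapped SST/chlorophyll, 1/12° currents/salinity) are
supported through the generic netCDF readers, but everything the tests and
the acceptance script exercise is generated by the synthetic module;
downloading, reprojection between CRSs, and cartographic map production are
out of scope.

## Climatological variables

Long-term means are per-pixel arithmetic means over all time steps with
valid data. A pixel must be valid in at least 50% of the steps entering a
mean (and, for the monthly climatology, 50% of the years of that calendar
month), else it is marked invalid; the satellite products this emulates do
not document a cloud-gap rule, so the threshold is a package choice and is
configurable (`min_valid_frac`). Max/Min SST are the pixel-level extremes
over the twelve monthly climatology grids, and a pixel missing any month is
invalid there — an extreme over a partial seasonal cycle would be biased
low/high. Avg SST comes from the monthly means directly, not from the
12-month climatology; current speed is averaged as per-time-step scalar
speed (a vector-mean magnitude would systematically under-read meandering
currents).

## Preprocessing

Coarse-grid variables are brought to the analysis grid by separable cubic
convolution ("bicubic") with kernel parameter a = −0.5 (Catmull-Rom), the
common default; it reproduces linear fields exactly and is implemented
directly because the interpolators in the scientific Python stack are
B-spline-based, which is a different cubic. Before interpolation, invalid
source cells are filled from their nearest valid cell so the 4×4 support
never mixes nodata into coastal values; the result is then re-masked at the
target resolution. Edge handling is replicate-padding.

Collinearity among the six variables is screened with Pearson correlation;
pairs with |r| ≥ 0.85 are reported and warned about but never dropped —
variable selection is the analyst's decision, and the package keeps all
six by default.

Each variable is standardized by its observed range over the sea pixels of
the cropped study region, `x → (x − min)/(max − min)`, so all six
contribute equally to the clustering; the fitted min/max travel with the
pipeline for exact inversion (`RangeScaler`). A constant column aborts:
a variable with no spread signals degenerate input, not a unit interval.
Standardization is applied after cropping and masking, so the unit interval
reflects the study region only.

## Batch SOM on a hexagonal lattice

Neurons sit on an odd-row-offset hexagonal lattice with X rows and Y
columns (interior degree 6; a 1×k lattice degenerates to a path — the
"linear" topology). The lattice metric is link distance: minimum adjacency
hops between neurons.

Training is batch, not online: step t assigns every row to its
best-matching unit by Euclidean distance in the standardized feature space
(ties to the lowest neuron index), then replaces each neuron's weight by
the mean of all rows whose BMU lies within link distance r(t); neurons
capturing no rows keep their weight, and no neuron is ever pruned. The
neighborhood is a hard indicator rather than a Gaussian, consistent with
integer link distances and exact batch means. The radius decays linearly
from 3 to 1 over the first 90% of the 1000 training steps (ordering phase)
and is 0 for the final 10% (convergence phase). With radius 0 the update
is exactly Lloyd's k-means iteration, so the final partition is a clean
Voronoi partition — the property the silhouette evaluation assumes.

Two numerical choices matter here:

* **Radius cap.** The effective radius is capped at (lattice diameter − 1).
  A hard-indicator neighborhood that spans the whole lattice replaces every
  weight by the global data mean in one step; once all weights are exactly
  identical, the tie rule sends every row to neuron 0 forever and the map
  can never de-collapse. The cap only affects small-diameter lattices
  (e.g. 1×2 through roughly 2×3); larger maps never reach it.
* **Cycle jumping.** At fixed effective radius the batch update is a
  deterministic map of the weight state, so the trajectory is eventually
  periodic — fixed points and short limit cycles (periods 2–12 are common)
  both occur. The trainer records visited states within each
  constant-radius stretch and, on the first revisit, jumps ahead by the
  remaining step count modulo the cycle length. This is exactly equivalent
  to evaluating every step and roughly 5× faster. The early stop
  (max weight change < 1e-9) applies only in the convergence phase,
  where it is a genuine fixed-point test.

Weight initialization: `pca_plane` (default) lays the lattice on the plane
of the first two principal directions of the data, spanning mean ± 2 SD
along each, with the longer lattice axis carrying the first direction and
single-row/column lattices using one direction only — fully deterministic.
`random` draws uniformly inside the per-column data range. `sample_d2`
seeds weights at data rows drawn with probability proportional to squared
distance from the nearest already-chosen seed, spreading the initial
weights over the occupied regions of feature space.

Diagnostics mirror the standard SOM plots: per-edge Euclidean weight
distances (the U-matrix content, large values marking class boundaries)
and per-variable weight planes (column slices of the weight matrix).

## Scenario scan and silhouette selection

Scenarios are all unordered factor pairs {X, Y} with X·Y in the scan range
(default 4–25), the 1×k linear arrangements included; the default range
contains exactly 43 scenarios. (Ordered-pair counting would double the
two-dimensional arrangements and is not used.)

Each scenario's partition is scored by the mean silhouette index
SI_i = (b_i − a_i)/max(a_i, b_i) with a_i the mean within-cluster distance
from point i and b_i the minimum mean distance to another cluster,
distances Euclidean in standardized space; singleton points score 0. For
inputs above `si_sample` points (default 10 000) the index is evaluated on
one seeded uniform subsample, with distances taken within the subsample;
the same subsample is shared by all scenarios so their scores are directly
comparable, and small inputs are evaluated in full. The implementation
aggregates cluster-mean distances from the pairwise matrix and is verified
against a literal O(n²) oracle to 1e-12.

Deterministic topology-ordered training can land in locally optimal
partitions of cleanly separated data — in recovery experiments the planted
partition's silhouette exceeded the trained map's on the seeds where
selection went wrong, i.e. the optimizer, not the criterion, was the weak
link. Each scenario therefore also considers two convergence-phase-only
candidates (radius 0 throughout, `sample_d2` initialization under spawned
seeds) and is represented by whichever candidate scores the highest mean
SI, ties keeping the neighborhood-trained map. The scenario with the
highest mean SI wins; exact ties go to the smaller neuron count and then
the smaller X (the more linear arrangement). A scenario whose best map
leaves fewer than two non-empty clusters is recorded with SI −1 and
flagged invalid rather than aborting the scan.

## Class characterization

The selected partition is summarized per class: mean and population SD
(divide-by-n; the classes are full pixel enumerations, not samples —
configurable) of each raw-unit variable over all of the class's pixels,
and the percentage of the seascape-of-interest polygon the class covers,
normalized by the classified pixels inside that polygon, so classes lying
entirely outside it score 0 and the in-polygon shares sum to 100. The
per-variable (min, max, max − min) of class means quantifies how strongly
the classes differ. Class numbers are neuron indices of the selected map
and are arbitrary up to permutation; all comparisons against external
summaries must be permutation-invariant. The real seascape polygon is a
user-supplied mask; the synthetic pipeline ships a stand-in (the bounding
box inset by 10% per side). A published nine-class summary of the Sunda
Banda delineation ships with the package for range arithmetic and as a
reference layout.

## Synthetic data: what it emulates, and what it does not

Generators are bit-reproducible under a single integer seed. Land is a
smoothed-noise field thresholded at its empirical quantile (blob-like,
achieved fraction exact to one cell). Regimes are a nearest-seed (Voronoi)
partition of the sea cells around K uniformly drawn seed cells: contiguous,
irregular regions with strongly varying sizes, resembling oceanographic
provinces. Regime signatures are drawn uniformly in span-standardized
[0,1]⁶ with a rejection step enforcing a minimum pairwise Euclidean
separation (default 0.5), then mapped to plausible physical spans
(chlorophyll through log space). Fields are signature plus spatially
smoothed Gaussian noise with per-variable SD = 4% of the variable's span
(so the default separation is ≈12.5 per-variable noise SDs, comfortably
above the 5-SD regime the recovery experiments assume); chlorophyll is
lognormal with the signature as its arithmetic mean, and Max SST is built
as Min SST plus a non-negative excess so the ordering holds pixelwise by
construction. Monthly stacks superpose a sinusoidal seasonal cycle (the 12
sampled phases sum to zero, so the noiseless long-term mean is exact) and
white monthly noise; the pipeline anchors the cycle to the planted Max/Min
fields so the derived climatology recovers them. Currents/salinity
analogues are generated at one third the grid resolution to exercise the
regridding step, mirroring the 1/12° → 4 km step of the real inputs.

None of this mimics real Indonesian Throughflow physics: there are no
fronts, advection, trends or cloud-correlated gaps, and regime boundaries
are sharp rather than gradual. Passing recovery tests therefore shows the
machinery finds planted piecewise-constant structure under realistic noise
and geometry — not that real seascape classes are as crisp.

## Problem sizes and defaults

The standard synthetic study runs on a 60×60 grid over the study box
(≈3 240 sea pixels at the default 10% land), K = 9 regimes, 11 years of
monthly data, 1000 training steps, initial radius 3, scan 4–25 with two
refinement restarts per scenario, full-data silhouette below the 10 000
subsample threshold. A full scan at these sizes takes tens of seconds on
one core; the grid is configurable up to the 4-km-style resolution of the
real products (~300×550), where the silhouette subsample and per-scenario
cost dominate.

## Known limitations

* Silhouette on a subsample estimates the full-data index; for strongly
  imbalanced classes a small subsample can miss tiny classes (the scan
  falls back to full data if a subsample degenerates to one cluster).
* The deterministic PCA-plane map alone is not a reliable global optimizer;
  the refinement restarts mitigate but do not guarantee recovery of the
  silhouette-optimal partition for every seed.
* Range standardization is sensitive to single-pixel outliers in the
  min/max; robust or z-score scaling is deliberately not in the default
  path.
* The netCDF writer targets the netCDF3 (scipy) backend: wide
  compatibility, no compression; class maps are int32 with 0 as nodata.
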
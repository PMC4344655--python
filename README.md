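# seascapes

Unsupervised delineation of biophysical marine environments ("seascape
bioregionalization") from gridded ocean climatologies, built around a batch
self-organizing map (SOM) on hexagonal lattices and silhouette-based
selection of the number and arrangement of classes.

The package targets the kind of analysis used to partition the Sunda Banda
Seascape (113–135°E, 0–13°S, central Coral Triangle) into biophysical
regions for marine spatial planning: six per-pixel variables — long-term
mean sea-surface temperature (Avg SST), the maximum and minimum of the
monthly SST climatology (Max/Min SST), long-term mean chlorophyll *a*,
current speed and salinity — are derived from monthly/daily stacks, brought
onto one 4-km-style grid, range-standardized, and clustered. A seeded
synthetic-data module generates inputs with the statistical structure the
analysis assumes (planted contiguous regimes with distinct six-variable
signatures, seasonal monthly stacks, blob-like land masks, coarse grids
that exercise regridding), so the entire pipeline runs and is tested with
no downloads.

## Method

Pixels are rows of a feature matrix `X ∈ [0,1]^{n×6}` after per-variable
range standardization `x → (x − min)/(max − min)`. A SOM with `k = X·Y`
neurons on a hexagonal lattice is batch-trained: each iteration assigns
every pixel to its best-matching unit (BMU, nearest neuron weight in
Euclidean distance) and replaces each neuron's weight by the mean of all
pixels whose BMU lies within link distance (lattice hops) `r(t)` of it;
`r(t)` decays linearly from 3 to 1 over the first 90% of 1000 iterations,
then is 0 (pure per-neuron mean refinement, i.e. Lloyd iterations), so the
final labeling is a Voronoi partition of the pixels by neuron weights.

Candidate maps with 4–25 neurons in every unordered lattice arrangement
{X, Y} — 43 scenarios, including the 1×k "linear" topologies — are scored
by the mean silhouette index

```
SI_i = (b_i − a_i) / max(a_i, b_i)
```

with `a_i` the mean distance from pixel *i* to its own cluster's other
pixels and `b_i` the smallest mean distance to another cluster; the
scenario with the highest mean SI is selected (ties → fewer neurons, then
the more linear arrangement). The selected partition is summarized per
class (area share of the seascape polygon, mean ± SD of each raw-unit
variable) and exported as an integer class map with the neuron-distance
(U-matrix) and per-variable weight-plane diagnostics.

## Worked example

```python
import numpy as np
from seascapes import (SynthConfig, make_truth, sbs_geo, synth_variable_fields,
                       build_feature_table, range_standardize, TopologyScan)

geo = sbs_geo(60, 60)                      # study box at 60x60 cells
cfg = SynthConfig(K=9, seed=1)             # 9 planted regimes
truth = make_truth(geo, cfg)
fields = synth_variable_fields(truth, cfg)
table = build_feature_table(fields, truth.sea_mask)
std, params = range_standardize(table)

scan = TopologyScan(k_min=4, k_max=25, random_state=1).fit(std.values)
best = scan.best_
print(f"best scenario {best.scenario.X}x{best.scenario.Y}, "
      f"{best.n_nonempty} classes, mean SI {best.mean_si:.4f}")

from sklearn.metrics import adjusted_rand_score
true_labels = truth.labels[table.pixel_index[:, 0], table.pixel_index[:, 1]]
print(f"ARI vs planted truth: {adjusted_rand_score(true_labels, scan.labels_):.3f}")
```

prints

```
best scenario 1x9, 9 classes, mean SI 0.7808
ARI vs planted truth: 1.000
```

— the scan recovers the nine planted regimes exactly (adjusted Rand index
1.0) and prefers the linear 1×9 arrangement among the scenarios attaining
that partition. The same analysis runs from the shell:

```bash
seascapes run-all -o runs/demo --seed 1      # all stages + manifest
seascapes scan -c config.yml -o runs/demo    # or stage by stage
```

Outputs land in the run directory: the six variable grids (netCDF), the
feature table and standardization parameters, the 43-scenario silhouette
table, the selected SOM model, the integer class map, the per-class summary
table, U-matrix edge distances and weight planes, and a `manifest.json`
with content hashes — reruns with the same config and seed are
bit-identical.

## Layout

- `seascapes.grids` — geolocated rasters and monthly stacks, netCDF I/O,
  cropping, mask algebra
- `seascapes.synthetic` — seeded generators for planted regimes, fields,
  stacks, land masks
- `seascapes.climatology` — long-term means, monthly climatologies and
  their pixel-level extremes
- `seascapes.features` — cubic-convolution regridding, collinearity
  screening, `RangeScaler`, feature-table assembly
- `seascapes.som` — hexagonal lattices, link distances, batch training,
  `HexSOM` estimator, U-matrix/weight-plane diagnostics
- `seascapes.selection` — scenario enumeration, silhouette index,
  `TopologyScan` estimator, best-partition selection
- `seascapes.characterize` — per-class summaries, class-mean ranges, class
  map export, shipped reference summary
- `seascapes.pipeline` / `seascapes.cli` — staged orchestration with a
  hashed manifest; `seascapes` console command

See `docs/methods.md` for the modeling choices, defaults and limitations.
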
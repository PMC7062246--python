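# habrisk

A seeded, config-driven pipeline for presence–background habitat-suitability
modelling and invasion-risk mapping: occurrence cleaning, two
background-generation schemes, predictor screening, a five-algorithm model
stage with quality gates, cross-validated evaluation, four thresholding
rules, binary-map ensembles, environmental-similarity (MESS) surfaces,
permutation variable importance, and management-unit risk summaries — all
testable end-to-end on synthetic virtual-species landscapes with known
truth.

## Layout

| module | contents |
| --- | --- |
| `habrisk.raster` | planar `RasterGrid`/`RasterStack` with ESRI ASCII-grid text I/O |
| `habrisk.occurrences` | load/filter/de-duplicate occurrence tables |
| `habrisk.background` | KDE background within a buffered minimum convex polygon; target-guild background within a 99% KDE isopleth |
| `habrisk.predictors` | nearest-neighbour grid harmonization, design-table extraction, max(|Pearson|,|Spearman|,|Kendall|) collinearity screen at 0.7 |
| `habrisk.sdm_models` | stepwise GLM, additive adaptive splines (GCV-pruned), boosted trees, random forest, maxent-style weighted logistic; overfitting (ΔAUC > 0.05) and quality (CV AUC < 0.7) gates with one automated re-tuning pass |
| `habrisk.evaluation` | AUC-ROC (Mann–Whitney), AUC-PR (average precision), PCC/Kappa/TSS/sensitivity/specificity, sens=spec threshold, stratified seeded 10-fold CV |
| `habrisk.thresholds_ensemble` | MPP / 1% / 10% / max-sens+spec thresholds, equal-weight ensemble counts, MESS, permutation ΔAUC importance |
| `habrisk.risk_assessment` | zonal suitable area/percent per management unit, nearest-occurrence distance, independent-point ensemble histograms |
| `habrisk.synthetic_fixtures` | Gaussian-random-field landscapes, virtual species, biased presence sampling |
| `habrisk.workflow` / `habrisk.cli` | config-driven end-to-end run with a replayable manifest |

## Conventions

- **Cell ownership** is half-open everywhere: a point on a vertical cell
  edge belongs to the cell on its right; a point on a horizontal edge to
  the cell above it (larger y). See `habrisk.raster`.
- **Suitable** always means *score ≥ threshold*.
- Percentile thresholds use the exclusion convention: the threshold is the
  (⌊q·n⌋+1)-th smallest presence score, so exactly ⌊q·n⌋ training presences
  are classified unsuitable.
- Coordinates are assumed already projected to a planar equal-area system;
  distances and areas are planar.
- Rasters are read/written as single-band ESRI ASCII grids (plain text)
  with `-9999` nodata; polygons as GeoJSON.

## CLI

```bash
# synthesize a complete input bundle (rasters, occurrences, targets, units)
habrisk make-fixture fixtures/ --seed 1 --shape 96 --n-presences 300

# full pipeline from a YAML config (see habrisk.workflow.RunConfig fields)
habrisk run config.yaml

# replay a previous run identically from its manifest alone
habrisk replay out/manifest.json

# individual stages
habrisk clean-occurrences raw.csv clean.csv --min-year 1980 --max-uncertainty-m 30
habrisk screen-variables design.csv screen_out --threshold 0.7
```

A run writes, into the configured output directory: cleaned occurrences +
filter log, background CSVs and extent GeoJSONs, correlation matrices and
removal logs, per-model metrics (train and 10-fold CV, per-fold long
table), per-model suitability and MESS rasters, four ensemble-count
rasters, permutation-importance CSV, per-unit risk CSV, an
independent-point evaluation histogram, and a `manifest.json` recording
every seed, setting, and gate decision (sufficient to replay the run).

## Notes on algorithm fidelity

- The maxent-style model is a background-weighted penalized logistic
  regression on linear + quadratic + hinge features (the weighted-logistic
  equivalence), not the Java Maxent implementation.
- The adaptive-spline model is implemented directly (forward hinge-pair
  growth, backward pruning by generalized cross-validation, penalty 2.0,
  additive degree 1) since no maintained Python implementation exists.
- Boosted trees use bag fraction 0.5 with the tree count chosen by an
  internal 20% holdout; all defaults are recorded in the run manifest.
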
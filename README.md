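# rangeshift

An ensemble species-distribution-modelling (SDM) pipeline for projecting
climate-driven range shifts: from raw occurrence records and monthly climate
grids to habitat-suitability ensembles, binary range maps, and
range-change / centroid-shift / altitude-shift statistics. A fully seeded
synthetic-data generator replaces external occurrence/climate downloads, so
the entire workflow is testable offline with known ground truth.

## What it does

1. **Synthetic inputs** (`rangeshift.synthetic_data`) — spatially
   autocorrelated monthly temperature/precipitation fields, an elevation
   model coupled to temperature through a lapse rate, a latent "true"
   suitability that is a logistic function of temperature seasonality and a
   Thornthwaite-style aridity index, and occurrence records sampled
   proportionally to that truth (with configurable fractions of pre-1970,
   high-uncertainty and duplicated records to exercise the cleaning rules).
2. **Occurrence preparation** (`rangeshift.occurrence_prep`) — temporal and
   coordinate-uncertainty filtering, per-cell deduplication, a buffered
   alpha-hull extent of occurrence, great-circle spatial thinning, and
   environmental (niche-space) thinning.
3. **Predictors** (`rangeshift.predictors`) — the 19 bioclimatic layers
   (bio4 uses the population-SD convention; bio15 the "+1 mm" offset),
   Thornthwaite PET / aridity, five terrain layers (Horn slope/aspect,
   heat load, TPI, TRI), stepwise Spearman + VIF collinearity screening,
   and per-location annual temperature-seasonality time series.
4. **Models** (`rangeshift.models`) — 30k-point background sampling,
   2x2 spatial-block cross-validation, a maxnet-style MaxEnt
   (linear/quadratic/hinge features, L1-penalized weighted logistic
   regression, cloglog output, omission-rate tuning over feature classes x
   regularization multipliers 1.0-10.0), random forests and boosted trees
   with permutation-importance variable reduction, and a bootstrap tree
   ensemble exposing per-cell uncertainty.
5. **Evaluation** (`rangeshift.evaluation`) — AUC, AUC-PR, TSS, Sørensen,
   Cohen's kappa, Brier score, Continuous Boyce Index; maxSSS and
   max-Sørensen thresholds; omission rates.
6. **Ensembles & projection** (`rangeshift.ensemble_projection`) — TSS >= 0.6
   member gating, five combination methods (median, mean, TSS-weighted mean,
   committee average, PCA), clamping masks and uncertainty masks.
7. **Range dynamics** (`rangeshift.range_dynamics`) — binarization,
   unlimited-dispersal loss/gain/overall-change percentages, occurrence-loss
   percentages, median centroids and great-circle distance matrices, mean
   altitudes, and Kruskal-Wallis / pairwise Wilcoxon (Holm) shift tests.
8. **Pipeline & CLI** (`rangeshift.pipeline`, `rangeshift.cli`) —
   config-driven orchestration with a reproducible JSON manifest.

## CLI

```bash
# write synthetic climate + occurrence inputs to a directory
rangeshift synth -o synth_data --seed 1

# run the full pipeline (defaults, or a YAML config)
rangeshift run --seed 1 -o runs/demo
rangeshift run -c config.yaml

# summarize a finished run
rangeshift report runs/demo
```

A config YAML may set any `RunConfig` field, e.g.:

```yaml
seed: 1
grid_shape: [80, 80]
n_raw_occurrences: 700
thinning: [geo, env]
algorithms: [maxent, RF, BRT, bagged_trees]
tss_min: 0.6
outdir: runs/demo
```

Outputs per run: `manifest.json` (config hash, stage record counts,
artifacts), `study_area.geojson`, and per-thinning-branch CSVs
(`*_range_change.csv`, `*_range_change_means.csv`,
`*_centroid_distances_km.csv`). Rasters are plain-text ESRI ASCII grids.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact arithmetic
on the published range-change table, oracle-equivalence suites (thresholds
vs exhaustive scan, AUC vs pairwise ordering, collinearity filter vs
brute-force recheck, alpha-hull containment), synthetic-truth recovery
across 10 seeds (TSS gate, seasonality ranked top predictor, poleward
centroid shift), and Boyce-index sanity simulations.

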
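# hfprisk

Pipeline for relating change in cumulative human pressure to change in
species extinction risk:

1. **hfp_builder** — standardizes eight pressure layers (built environments,
   croplands, pastures, population density, night-time lights, railways,
   roads, navigable waterways) onto 0–10 scores and sums them into integer
   0–50 human-footprint (HFP) maps for two epochs, plus an increase-only
   change product (per-cell deltas and a 51×51 transition matrix).
2. **risk_transitions** — filters a Red List catalogue and classifies each
   species' category pair into low-/high-risk (and uplisted/not-uplisted)
   transitions; tabulates the category transition matrix and headline shares.
3. **range_overlap** — rasterizes range polygons onto the HFP grid
   (cell-center rule) and computes cumulative profiles, extent of range above
   each threshold `HFP > t` (t = 0…49), and its change between epochs with an
   optional "no change" clamp for per-cell decreases.
4. **sweep_stats** — per-threshold group curves with 95% bands, Cohen's d,
   one-sided rank-sum tests, and the effect-size peak across thresholds.
5. **risk_model** — random-forest classification of risk transitions from
   the two HFP predictors plus pressure/life-history/environmental
   covariates; stratified-CV accuracy, sensitivity, specificity,
   TSS (= sensitivity + specificity − 1), permutation and Gini importances,
   and TSS-based threshold selection.
6. **biogeography** — majority-rule realm/biome-realm assignment (> 50% of
   range), the ≥ 5 + ≥ 5 species filter, and per-realm sweeps/models.
7. **synthetic_data** — seeded generator for all inputs, with a planted
   logistic dependence of high-risk probability on the change in
   above-threshold extent at a chosen threshold `t_star` (ground truth
   emitted for parameter-recovery checks).
8. **cli / pipeline** — readers and writers (ESRI ASCII grid rasters,
   GeoJSON ranges, CSV tables, YAML config, JSON reports) and the umbrella
   CLI orchestrating all stages with a checksummed manifest.

Rasters are plain-text ESRI ASCII grids (`.asc`) rather than GeoTIFF so the
whole pipeline is text-only and dependency-light (no GDAL required).

## CLI

Every stage is a subcommand of `hfprisk` (see `hfprisk --help`):

```sh
hfprisk simulate --out-dir data/ --seed 1
hfprisk build-hfp --config cfg.yml --epoch 1993 --out hfp1993.asc
hfprisk hfp-change --a hfp1993.asc --b hfp2009.asc --clamp --out-matrix trans.csv
hfprisk classify --in data/categories.csv --out labels.csv --summary summary.json
hfprisk overlap --ranges data/ranges.geojson --hfp93 data/hfp1993.asc \
    --hfp09 data/hfp2009.asc --clamp --out overlaps.csv
hfprisk sweep --overlaps overlaps.csv --labels labels.csv --out sweep.csv
hfprisk model --overlaps overlaps.csv --covariates data/covariates.csv \
    --labels labels.csv --t 3 --seed 42 --out report.json
hfprisk select-threshold --overlaps overlaps.csv --covariates data/covariates.csv \
    --labels labels.csv --t-min 0 --t-max 9 --out curve.csv
hfprisk realms --realm-raster data/realms.asc --biome-raster data/biomes.asc \
    --legend data/realm_legend.json --ranges data/ranges.geojson \
    --overlaps overlaps.csv --labels labels.csv --out assignments.csv
hfprisk run-all --out-dir run/ --seed 1
```

`run-all` executes simulate → build-hfp → hfp-change → classify → overlap →
sweep → model → realms and writes `manifest.json` with SHA-256 checksums of
every output; reruns with the same config are byte-identical.

Thresholds are always the strict form `HFP > t`; a prose statement like
"HFP ≥ 3" corresponds to `t = 2`.

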
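# Data dictionary

## Observations CSV (canonical columns)

| column | type | meaning |
|---|---|---|
| `plot_id` | str | whole-plot identifier (richness level is randomised at this scale) |
| `subplot_id` | str | `<plot_id>-<treatment>`; the unit receiving one consumer-removal treatment |
| `richness` | int | planted species richness of the plot (1, 4 or 16 by default) |
| `treatment` | str | consumer-removal treatment label |
| `year` | int | calendar year of the observation |
| `doy` | int | Julian day of year, 1-based, in [1, 366] |
| `red` | float | red-band reflectance fraction in [0, 1]; optional |
| `nir` | float | near-infrared reflectance fraction in [0, 1]; optional |
| `ndvi` | float | (NIR − Red)/(NIR + Red), in [−1, 1]; optional if both reflectances present |

Foreign headers are remapped through the `dialect` mapping in the config
(canonical name → file header). Rows failing validation are written to a
validation report CSV with columns `row` (0-based data row index) and
`reason` (one of `doy-out-of-range`, `red-out-of-range`,
`nir-out-of-range`, `ndvi-out-of-range`, `no-response`,
`unparseable: ...`).

## Metrics CSV (one row per subplot-year series)

| column | units | meaning |
|---|---|---|
| `subplot_id`, `year`, `plot_id`, `richness`, `treatment` | — | series identity, carried from the observations |
| `indvi_total` | NDVI·days | integral of the smoothing spline over the observed span |
| `indvi_early` | NDVI·days | integral from the span start to `boundary_doy` |
| `indvi_late` | NDVI·days | integral from `boundary_doy` to the span end |
| `spline_r2` | — | R² of the smoothing spline on the observed points; case weight for INDVI models |
| `peak_doy` | day | day of the maximum observed NDVI (ties → earliest) |
| `peak_ndvi` | — | the maximum observed NDVI value |
| `doy_min`, `doy_max` | day | first and last observed days (the spline's span) |
| `greenup_slope` | NDVI/day | OLS slope of NDVI on doy for observations at or before the peak |
| `greenup_r2` | — | R² of that regression; case weight for green-up models |
| `senescence_slope` | NDVI/day | OLS slope at or after the peak (negative for unimodal seasons) |
| `senescence_r2` | — | R² of that regression; case weight for senescence models |
| `boundary_doy` | day | early/late split day used for the partition mode of the run |
| `reason_codes` | — | semicolon-joined flags: `constant-series`, `greenup-underdetermined`, `senescence-underdetermined` |

Metrics that cannot be computed are NaN with a reason code, never zero.

## Excluded-series CSV

`subplot_id`, `year`, `reason` — one row per series dropped by coverage
filtering; reasons are `early-season undersampled`,
`late-season undersampled` or `fewer than 4 observations`.

## LS-means CSV (per response)

`richness`, `treatment`, `lsmean`, `se`, `ci_low`, `ci_high` — estimated
marginal mean per factorial cell with SE and 95% CI (±1.96·SE). The header
comment line records the response, weighting, partition mode and seed that
produced the table.

## Variance-components CSV (per response)

`year`, `plot`, `subplot`, `residual` — REML variance estimates (response
units squared). A component at zero indicates a singular (boundary) fit.

## Contrasts CSV

| column | meaning |
|---|---|
| `response` | metric being contrasted |
| `factor` | `richness` or `treatment` (margins averaged over the other factor) |
| `level`, `reference` | the contrasted level and its reference (lowest richness / control) |
| `difference`, `difference_se` | level − reference on the response scale |
| `percent`, `percent_se` | 100·(level − reference)/reference with delta-method SE; empty when the reference mean is not positive (e.g. negative senescence slopes) |

## Figure tables

`figure_indvi_whole_season.csv`, `figure_indvi_early_late.csv`,
`figure_slopes.csv`, `figure_peak_day.csv` — LS-means tables stacked per
response group, one row per treatment cell, for plotting means with 95%
CIs.

## Provenance JSON

`version`, `seed`, `partition_mode`, `responses`, `input_checksum_sha256`
(SHA-256 of the input file, or of the simulated canonical CSV),
`config` (full echo), `n_series_retained`, `n_series_excluded`. A run is
re-derivable from this record alone.
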
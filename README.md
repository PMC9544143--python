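# greenwave

Phenology metrics and treatment inference for NDVI time series from
factorial grassland experiments.

Field experiments that cross planted species richness (whole plots) with
consumer-removal treatments (pesticide subplots) often monitor productivity
with a handheld radiometer: every two weeks from spring to late summer, one
NDVI reading per subplot. `greenwave` turns those readings into
season-level phenology metrics and estimates how richness and consumer
removal — and their interaction — shift them.

## What it computes

For each subplot-year NDVI series (NDVI = (NIR − Red)/(NIR + Red)):

- **INDVI** — the integral of a cubic smoothing spline fitted to NDVI vs
  day of year (smoothing chosen by generalized cross-validation), over the
  whole observed season and over its early and late halves
  (units NDVI·days). A proxy for cumulative production.
- **Green-up and senescence slopes** — OLS slopes of NDVI on day of year
  using observations up to / from the day of maximum observed NDVI
  (units NDVI/day), with their regression R².
- **Peak timing** — the Julian day of the maximum observed NDVI.

Each metric *y<sub>ijkt</sub>* (subplot *k* in plot *j*, year *t*) is then
modelled with a weighted linear mixed model

> *y* = μ(richness × treatment) + *u*<sub>year</sub> + *u*<sub>plot</sub> +
> *u*<sub>subplot</sub> + ε,  ε<sub>i</sub> ~ N(0, σ²/w<sub>i</sub>)

fit by REML, where the case weight *w<sub>i</sub>* is the fit R² of the
upstream spline or phase regression, so poorly characterised series carry
less weight. Effect sizes are reported as least-square means per treatment
cell, percent differences between cells or margins (delta-method SEs), and
day differences for peak timing. A likelihood-ratio test screens for AR(1)
correlation of residuals across years within a subplot.

A synthetic-data module simulates the whole experiment from a
double-logistic seasonal curve with known richness/treatment effects and
hierarchical noise, so every stage can be validated against ground truth.

## Worked example

```python
from greenwave import build_design, simulate_experiment, assemble_series, metrics_table
from greenwave import CurveParams, VarianceConfig, SamplingSchedule, reference_effects
from greenwave import ModelSpec, fit_lmm, lsmeans, percent_contrast, day_contrast

design = build_design({1: 15, 4: 9, 16: 9}, years=range(2010, 2015))
records = simulate_experiment(design, CurveParams(), reference_effects(),
                              VarianceConfig(seed=42), SamplingSchedule())
metrics = metrics_table(assemble_series(records))
print(f"{len(metrics)} subplot-year series; mean spline R2 = {metrics.spline_r2.mean():.3f}")

fit = fit_lmm(metrics, ModelSpec(response="indvi_total"))
over = percent_contrast(lsmeans(fit), ("richness", 16), ("richness", 1))
print(f"INDVI overyielding, 16 spp vs monoculture: "
      f"{over.percent:.1f}% (SE = {over.percent_se:.2f})")

peak = fit_lmm(metrics, ModelSpec(response="peak_doy"))
shift = day_contrast(lsmeans(peak), ("richness", 16), ("richness", 1))
print(f"peak NDVI shift, 16 spp vs monoculture: "
      f"{shift.difference:.1f} days (SE = {shift.difference_se:.2f})")
```

prints

```
825 subplot-year series; mean spline R2 = 0.992
INDVI overyielding, 16 spp vs monoculture: 58.6% (SE = 3.41)
peak NDVI shift, 16 spp vs monoculture: -26.9 days (SE = 1.02)
```

The simulation applied a 1.6× amplitude multiplier and a −26-day phenology
shift to 16-species plots; the recovered overyielding percentage (on raw
INDVI, which still contains the bare-ground baseline) and the recovered
peak shift line up with those generating effects.

## Command line

```sh
greenwave run      --config cfg.yaml --seed 7 --out results/
greenwave simulate --config cfg.yaml --out data.csv
greenwave metrics  --in data.csv --partition median_doy --out metrics.csv
greenwave fit      --in metrics.csv --response indvi_total --out models/
greenwave report   --in metrics.csv --out report/
```

The YAML config chooses exactly one input source (a canonical-column CSV or
a synthetic design), the season partition mode (`median_doy`,
`median_count` or `peak_doy`), coverage filtering, and the responses to
model; unknown keys are rejected. Every run emits a provenance record
(config echo, package version, input checksum) from which its outputs can
be re-derived. See `docs/methods.md` for the model details and
`docs/data_dictionary.md` for all output columns.

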
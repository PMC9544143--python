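# Methods

## Experimental design model

The design is split-plot: whole plots carry a planted species-richness
level (1, 4 or 16 species; 15/9/9 plots by default, 33 in all) and each
plot contains one subplot per consumer-removal treatment (control,
insecticide, foliar fungicide, soil fungicide, all pesticides combined) —
165 subplots and 15 richness × treatment combinations. Subplot identifiers
are `<plot_id>-<treatment>`, so joins never need a lookup table, and
`build_design` is deterministic: the same inputs always enumerate the same
identifiers.

## From reflectance to season series

NDVI is computed as (NIR − Red)/(NIR + Red) from reflectance fractions;
the ratio is undefined when both bands are zero and that case is an error,
not a silent NaN. Ingest validates every row (day of year in 1–366,
reflectances in [0, 1], NDVI in [−1, 1]) and reports rejected rows with
reason codes rather than dropping them. Observations are grouped into one
series per subplot-year; same-day replicate readings are averaged — a
single radiometer pass per visit is the norm, and averaging is the least
information-destroying merge.

**Coverage filtering.** A series is usable only if it characterises the
whole season: at least `min_per_half` observations (default 2) on each
side of a boundary day and at least 4 points overall. The boundary
defaults to the per-year median observed day across all subplots, so the
rule adapts to each year's campaign rather than a fixed calendar date; a
fixed boundary can be supplied instead. The minimum per half is a free
parameter — no principled value exists, and 2 is the smallest count that
distinguishes "sampled" from "a single stray visit". Exclusions carry
machine-readable reason codes and the filter partitions its input exactly.

## Spline metrics

**Smoothing spline.** Each series is fit with a natural cubic smoothing
spline minimising Σ(y − f)² + λ∫f″², with λ selected by generalized
cross-validation. The implementation uses the Reinsch form: one
eigendecomposition of the curvature penalty matrix makes the GCV score
n·RSS/tr(I − A)² an O(n) function of λ, which is minimised by a coarse
log-grid scan (the GCV profile can be multimodal) plus bounded local
refinement. The smoothing spline is then recovered as the natural cubic
interpolant of its own fitted values — the two coincide exactly — and
integrals use the exact piecewise-polynomial antiderivative, so the
1e−8 relative integration tolerance is trivially met. Tests verify the
fitted values against `scipy.interpolate.make_smoothing_spline` at the
same λ and check that the selected λ is a GCV minimum of the
independently evaluated criterion.

Four observations are the eligibility floor; with exactly four points
there are no residual degrees of freedom for GCV and the interpolating
natural cubic (the λ → 0 limit) is used. A constant series has zero total
sum of squares; its R² is reported as 1 by convention and the fit is
flagged. The spline is an interpolant only: evaluation or integration
outside the observed day range is an error.

**Season partition.** Three modes split a series into early and late
halves: `median_doy` (boundary at the series' median observed day, the
default), `median_count` (ordered list split at the midpoint index; odd
counts share the middle observation), and `peak_doy` (boundary at the
observed peak day). An observation exactly on the boundary belongs to both
halves so the two integration windows stay contiguous; early + late INDVI
equals whole-season INDVI to integration tolerance by construction.

**Peak and slopes.** Peak timing is the day of the maximum *observed*
NDVI (ties to the earliest day), not the spline maximum — the metric is
defined on values, and the phase regressions are fit to raw values on
either side of it. The peak observation anchors both regressions: the
pre/post wording is ambiguous at the peak itself, and inclusion stabilises
three-point fits symmetrically. A phase with fewer than three points
yields a missing metric with a reason code, never a fabricated zero.

R² values from the spline and from each phase regression are carried into
the metrics table unmodified; they become case weights downstream. Poor
linear fits can have R² near zero, so weights are floored at 0.01 to stay
positive.

## Synthetic data generator

The generating curve is the double logistic

ndvi(t) = B + A·[1/(1 + e^{−g(t−t_g)}) − 1/(1 + e^{−s(t−t_s)})],

the standard remote-sensing phenology form, chosen because its parameters
map directly onto the metrics: amplitude A drives INDVI, t_g/t_s set the
green-up and senescence midpoints, g/s the phase steepness. Defaults
(B = 0.05, A = 0.45, t_g = 140, g = 0.15, t_s = 230, s = 0.10) describe a
monoculture-like curve peaking near 0.5 in mid-July, leaving headroom
below the NDVI ceiling for overyielding multipliers.

Treatment structure enters as multipliers and shifts on the cell's curve:
richness scales A and shifts (t_g, t_s) jointly; treatment scales the
senescence rate s; an optional (richness, treatment) amplitude multiplier
creates interactions. The "reference" preset — amplitude ×1.0/1.25/1.6
and phenology shift 0/−10/−26 days for 1/4/16 species, senescence ×0.65
wherever foliar fungicide is applied — is a synthetic preset with
qualitatively realistic magnitudes for recovery testing, not a set of
field estimates.

Hierarchical noise enters as additive random intercepts on A (year, plot,
subplot; SDs 0.03/0.03/0.02 by default, i.e. a few percent of a typical
amplitude) plus residual NDVI noise (SD 0.03; within-season radiometer
noise is not reported in the field literature we model, so this is a free
parameter). Random effects act on amplitude rather than on NDVI directly
so curves stay unimodal and inside [−1, 1]; final values are clipped as a
guard. Sampling follows a biweekly April–August schedule (days 105–240,
interval 14) with ±2 days of visit jitter and optional missed visits.
Every random draw comes from a stream keyed by (seed, role, plot,
treatment, year), so output is identical regardless of iteration order.

What the generator does *not* emulate: weather-driven year shapes (year
effects only scale amplitude), spatial autocorrelation between plots,
multi-peak seasons, sensor drift. Passing recovery tests therefore show
the pipeline recovers effects under a correctly specified unimodal world,
not that the field data meet those assumptions.

`true_metrics` provides the generator's ground truth (peak by grid search
refined with bounded golden-section, INDVI by adaptive quadrature at
1e−8 relative tolerance); a flat curve (A = 0) has no peak and raises an
explicit error.

## Mixed models

Fixed effects are the full richness × treatment cell structure, fit in
cell-means form (equivalent to the saturated two-factor model); random
intercepts are year (crossed with plots), plot, and subplot within plot —
subplot identifiers already encode their plot, so the nesting is implicit
in the coding. Case weights multiply residual precision
(Var(ε_i) = σ²/w_i), the conventional reading of "higher-R² series weigh
more"; estimates are invariant to rescaling all weights, and the R² is
used raw (with the 0.01 floor) rather than normalised or truncated —
any monotone rescaling choice is arbitrary, so the simplest is documented.

The engine profiles the likelihood over the fixed effects and σ²,
optimising only the variance ratios (on the SD-ratio scale, where zero is
an ordinary point of the parameter space) and, when requested, the AR(1)
correlation ρ. Marginal covariance inverses use the Woodbury identity in
its √Γ form so a ratio of exactly zero is harmless; a component estimated
at (numerically) zero flags the fit as singular rather than failing.
Reported fits use REML; the AR(1) likelihood-ratio comparison refits both
models by ML, as required for comparing correlation structures. When the
response lies exactly in the span of the cell means (all noise sources
zero), the fit short-circuits to OLS with zero variance components —
fitted cell means then equal the cell values exactly. The engine is
checked against statsmodels `MixedLM` (single grouping, unweighted) and
lme4's `lmer` (weighted, crossed/nested) in the test suite; neither
supports the weighted-plus-AR(1) combination, which is why the engine
exists.

Richness enters as a categorical factor (3 levels); a log₂(richness)
linear coding would use the same machinery but is not the default, since
three levels leave the saturated categorical fit estimable and
assumption-free.

**LS-means and contrasts.** With cell-means coding, estimated marginal
means are the coefficients themselves and margins average cells with
equal weight (the least-square-means convention), with SEs from the full
fixed-effect covariance. Percent differences 100·(μ_a − μ_b)/μ_b get
first-order delta-method SEs, validated against a parametric bootstrap in
tests; a non-positive denominator leaves the percentage undefined and
returns the absolute difference. Peak-day effects are reported as day
differences. Confidence intervals are mean ± 1.96·SE.

**AR(1) screen.** ρ is estimated in (−0.95, 0.95), so ρ = 0 is interior
and the LRT statistic is referred to χ²(1); had ρ been constrained
non-negative, the 50:50 mixture of χ²(0) and χ²(1) would apply and the
χ²(1) reference would be conservative. Calibration is checked by
simulating 200 null datasets directly from the mixed model (12 plots × 5
treatments × 5 years) — the null concerns the model layer, so simulating
at metric level rather than re-running the spline pipeline tests the same
hypothesis at a fraction of the cost.

## Study sizes used in validation

The effect-recovery study runs the full pipeline (simulate → splines →
weighted LMM → margin contrasts) at the reference preset on the 33-plot
design over 5 years (825 series per replicate), 100 replicates in the
test suite, comparing recovered 16-vs-1 contrasts of baseline-corrected
INDVI (B·span subtracted, putting the percent contrast on the amplitude
scale) and peak day against `true_metrics` oracle values; 2-SE coverage
must reach 90%. A fully noiseless, jitter-free run checks the recovered
peak shift against −26 days within one sampling interval — observed peak
days are quantized to the biweekly visit grid, so ±14 days is the
resolution limit of the peak-day metric, not a model error.

## Known limitations

- GCV smoothing on ~10 points per season is variable; the spline R²
  weights partially compensate, but very short series are better excluded
  via the coverage filter than down-weighted.
- The delta-method SE for percent contrasts assumes the denominator mean
  is well away from zero; for baseline-level responses use absolute
  differences.
- The AR(1) screen shares variance parameters across treatment cells; it
  is a structure check, not a full serial-correlation model.
- Identifiability of the year variance component rests on only as many
  levels as there are study years; with fewer than ~5 years its estimate
  is poor (the fit is flagged singular when it hits zero).
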
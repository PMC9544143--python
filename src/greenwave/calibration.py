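"""Simulation studies: effect recovery and likelihood-ratio-test calibration.

These are full-pipeline experiments run against known generator truth: the
factorial design is simulated at the "reference" effect preset, pushed
through spline metrics and the weighted mixed models, and the recovered
margin contrasts are compared with oracle values computed directly from the
generating curves. They back both the test suite and the reproduction
script, so their problem sizes are part of the package's documented study
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DEFAULT_RICHNESS_COUNTS, TREATMENTS, build_design
from .inference import (ModelSpec, day_contrast, fit_lmm, lrt_year_correlation,
                        lsmeans, percent_contrast, simulate_lmm_dataset)
from .observations import assemble_series
from .phenology import metrics_table
from .simulate import (CurveParams, SamplingSchedule, VarianceConfig,
                       reference_effects, simulate_experiment, true_metrics)


@dataclass
class RecoveryConditions:
    """Study conditions for the reference effect-recovery experiment."""

    richness_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS_COUNTS))
    years: list[int] = field(default_factory=lambda: list(range(2010, 2015)))
    curve: CurveParams = field(default_factory=CurveParams)
    variance: VarianceConfig = field(default_factory=VarianceConfig)
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)

    @property
    def window(self) -> tuple[float, float]:
        s = self.schedule
        last = s.start_doy + ((s.end_doy - s.start_doy) // s.interval_days) \
            * s.interval_days
        return float(s.start_doy), float(last)


def truth_contrasts(cond: RecoveryConditions):
    """Oracle margin contrasts implied by the reference generating curves.

    Returns the true percent difference in baseline-corrected whole-season
    INDVI (16 species vs monoculture margins) and the true peak-day shift.
    """
    eff = reference_effects()
    window = cond.window
    span = window[1] - window[0]
    by_rich: dict[int, list[float]] = {}
    peak_by_rich: dict[int, list[float]] = {}
    for r in cond.richness_counts:
        for t in TREATMENTS:
            curve = eff.curve_for(cond.curve, r, t)
            peak, _, indvi = true_metrics(curve, window)
            by_rich.setdefault(r, []).append(indvi - curve.B * span)
            peak_by_rich.setdefault(r, []).append(peak)
    m = {r: float(np.mean(v)) for r, v in by_rich.items()}
    peaks = {r: float(np.mean(v)) for r, v in peak_by_rich.items()}
    return {
        "indvi_pct_16_vs_1": 100.0 * (m[16] - m[1]) / m[1],
        "peak_shift_16_vs_1": peaks[16] - peaks[1],
    }


def run_recovery_once(cond: RecoveryConditions, seed: int):
    """One pipeline pass at the reference preset; returns margin contrasts."""
    design = build_design(cond.richness_counts, TREATMENTS, cond.years)
    var = replace(cond.variance, seed=seed)
    records = simulate_experiment(design, cond.curve, reference_effects(),
                                  var, cond.schedule)
    series = assemble_series(records)
    metrics = metrics_table(series)
    metrics["indvi_total_bc"] = metrics["indvi_total"] - cond.curve.B * (
        metrics["doy_max"] - metrics["doy_min"])

    fit_i = fit_lmm(metrics, ModelSpec(response="indvi_total_bc",
                                       weights="spline_r2"))
    pct = percent_contrast(lsmeans(fit_i), ("richness", 16), ("richness", 1))
    fit_p = fit_lmm(metrics, ModelSpec(response="peak_doy", weights=None))
    shift = day_contrast(lsmeans(fit_p), ("richness", 16), ("richness", 1))
    # decline rate = -slope, so a percent contrast has a positive denominator;
    # a negative percent means slower senescence under the treatment
    metrics["senescence_rate"] = -metrics["senescence_slope"]
    fit_s = fit_lmm(metrics, ModelSpec(response="senescence_rate",
                                       weights="senescence_r2"))
    fungicide = percent_contrast(lsmeans(fit_s),
                                 ("treatment", "foliar_fungicide"),
                                 ("treatment", "control"))
    return {
        "indvi_pct": pct.percent, "indvi_pct_se": pct.percent_se,
        "peak_shift": shift.difference, "peak_shift_se": shift.difference_se,
        "senescence_pct": fungicide.percent,
        "senescence_pct_se": fungicide.percent_se,
    }


def recovery_study(n_seeds: int = 100, base_seed: int = 0,
                   cond: RecoveryConditions | None = None) -> pd.DataFrame:
    """Repeat the recovery experiment over seeds; one row per replicate,
    with coverage indicators for the two headline contrasts (estimate within
    2 SE of the generator truth)."""
    cond = cond or RecoveryConditions()
    truth = truth_contrasts(cond)
    rows = []
    for i in range(n_seeds):
        res = run_recovery_once(cond, seed=(base_seed + i) % 2**31)
        res["covers_indvi"] = (
            abs(res["indvi_pct"] - truth["indvi_pct_16_vs_1"])
            <= 2.0 * res["indvi_pct_se"])
        res["covers_peak"] = (
            abs(res["peak_shift"] - truth["peak_shift_16_vs_1"])
            <= 2.0 * res["peak_shift_se"])
        rows.append(res)
    return pd.DataFrame(rows)


def noiseless_recovery(cond: RecoveryConditions | None = None):
    """Deterministic run: no random effects, no noise, no jitter.

    Returns the recovered 16-vs-1 peak-day margin shift; observed peak days
    are quantized to visit days, so the shift can differ from the generator's
    -26 days by up to one sampling interval.
    """
    cond = cond or RecoveryConditions()
    cond = replace(
        cond,
        variance=VarianceConfig(sd_year=0, sd_plot=0, sd_subplot=0,
                                sd_resid=0, seed=0),
        schedule=replace(cond.schedule, jitter_days=0, miss_prob=0.0),
    )
    design = build_design(cond.richness_counts, TREATMENTS, cond.years)
    records = simulate_experiment(design, cond.curve, reference_effects(),
                                  cond.variance, cond.schedule)
    metrics = metrics_table(assemble_series(records))
    per_rich = metrics.groupby("richness")["peak_doy"].mean()
    return float(per_rich[16] - per_rich[1]), metrics


def lrt_type1_study(n_reps: int = 200, base_seed: int = 0,
                    n_plots: int = 12, n_years: int = 5) -> pd.DataFrame:
    """Type-I error of the AR(1)-by-year LRT under independent year effects.

    Responses are simulated directly from the mixed model with rho = 0 (the
    null of the test); each replicate runs the ML/ML likelihood-ratio
    comparison. The rejection rate at alpha = 0.05 should sit near 5%.
    """
    rows = []
    spec = ModelSpec(response="value", weights=None)
    for i in range(n_reps):
        df = simulate_lmm_dataset(n_plots=n_plots, treatments=5,
                                  n_years=n_years, rho=0.0,
                                  seed=(base_seed + i) % 2**31)
        res = lrt_year_correlation(df, spec)
        rows.append({"statistic": res.statistic, "pvalue": res.pvalue,
                     "reject": res.pvalue < 0.05})
    return pd.DataFrame(rows)


def lrt_power_study(n_reps: int = 200, base_seed: int = 0, rho: float = 0.8,
                    n_plots: int = 12, n_years: int = 8) -> pd.DataFrame:
    """Power of the AR(1) LRT under strong serial correlation."""
    rows = []
    spec = ModelSpec(response="value", weights=None)
    for i in range(n_reps):
        df = simulate_lmm_dataset(n_plots=n_plots, treatments=5,
                                  n_years=n_years, rho=rho,
                                  seed=(7_000_000 + base_seed + i) % 2**31)
        res = lrt_year_correlation(df, spec)
        rows.append({"pvalue": res.pvalue, "rho_hat": res.rho,
                     "prefer_ar1": res.preferred == "ar1"})
    return pd.DataFrame(rows)
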
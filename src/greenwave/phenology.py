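"""Per-series phenology metrics: INDVI, green-up/senescence slopes, peak timing.

Each subplot-year NDVI series is summarised by the integral of a GCV-selected
cubic smoothing spline (whole season, early and late halves), ordinary
least-squares slopes of NDVI on day of year before and after the observed
peak, and the day of the maximum observed NDVI. Fit-quality R-squared values
are retained for use as case weights in downstream mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .observations import SeasonSeries

#: floor applied to R-squared values used as model weights
WEIGHT_FLOOR = 0.01

PARTITION_MODES = ("median_doy", "median_count", "peak_doy")


def compute_ndvi(red, nir):
    """NDVI = (nir - red) / (nir + red), from reflectance fractions in [0, 1].

    Raises ValueError when red + nir = 0 (undefined ratio).
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any(red < 0) or np.any(red > 1) or np.any(nir < 0) or np.any(nir > 1):
        raise ValueError("reflectances must lie in [0, 1]")
    denom = nir + red
    if np.any(denom == 0):
        raise ValueError("NDVI undefined where red + nir = 0")
    out = (nir - red) / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class SplineFit:
    """A fitted smoothing spline for one series, with its fit-quality R²."""

    key: tuple[str, int]
    spline: CubicSpline
    lam: float                 # GCV-selected smoothing parameter (0 = interpolating)
    r2: float
    span: tuple[float, float]  # observed doy range; no extrapolation beyond it
    constant: bool = False     # degenerate flat series (SST = 0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.span[0] - 1e-9) or np.any(t > self.span[1] + 1e-9):
            raise ValueError(f"evaluation outside observed span {self.span}")
        out = self.spline(t)
        return float(out) if out.ndim == 0 else out


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    """Reinsch form of the curvature penalty: int f''(t)^2 dt = f' K f for a
    natural cubic spline with knots x, K = D' W^-1 D."""
    n = len(x)
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -(1.0 / h[i] + 1.0 / h[i + 1])
        D[i, i + 2] = 1.0 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def gcv_smoothing(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """(lambda, fitted values) minimising generalized cross-validation.

    The smoothing spline minimises sum (y - f)^2 + lambda int f''^2; in the
    Reinsch form the fitted values are (I + lambda K)^-1 y, so with one
    eigendecomposition of K the GCV score n*RSS/tr(I-A)^2 is O(n) per
    candidate lambda and can be minimised by bounded search on log-lambda.
    """
    n = len(x)
    d, U = np.linalg.eigh(_penalty_matrix(x))
    d = np.clip(d, 0.0, None)
    yt = U.T @ y

    def score(log10lam: float) -> float:
        shrink = 10.0**log10lam * d
        a = shrink / (1.0 + shrink)       # eigenvalues of I - A
        tr = float(np.sum(a))
        if tr <= 0:
            return np.inf
        return n * float(np.sum((a * yt) ** 2)) / tr**2

    # the GCV profile can be multimodal: coarse scan, then local refinement
    grid = np.linspace(-10.0, 12.0, 89)
    best = grid[int(np.argmin([score(g) for g in grid]))]
    res = minimize_scalar(score, bounds=(best - 0.5, best + 0.5),
                          method="bounded", options={"xatol": 1e-6})
    lam = 10.0**res.x
    fitted = U @ (yt / (1.0 + lam * d))
    return lam, fitted


def fit_spline(series: SeasonSeries) -> SplineFit:
    """Cubic smoothing spline of NDVI on day of year, smoothing chosen by GCV.

    Requires at least 4 observations; exactly 4 points leave no residual
    degrees of freedom for GCV and get the interpolating natural cubic, the
    zero-smoothing limit. The smoothing spline is recovered as the natural
    cubic interpolant of its own fitted values (they coincide exactly). A
    constant series has SST = 0; its R² is 1 by convention, flagged.
    """
    if len(series) < 4:
        raise ValueError(f"series {series.key} has {len(series)} < 4 observations")
    x = np.asarray(series.doy, dtype=float)
    y = np.asarray(series.ndvi, dtype=float)

    if len(x) >= 5:
        lam, fitted = gcv_smoothing(x, y)
    else:
        lam, fitted = 0.0, y
    spl = CubicSpline(x, fitted, bc_type="natural")

    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    constant = sst == 0.0
    r2 = 1.0 if constant else 1.0 - sse / sst
    return SplineFit(key=series.key, spline=spl, lam=lam, r2=r2,
                     span=(float(x[0]), float(x[-1])), constant=constant)


def integrate_indvi(fit: SplineFit, t0: float, t1: float) -> float:
    """Integral of the fitted spline over [t0, t1] (NDVI·days).

    The window must lie inside the observed span: the spline is an
    interpolant, never an extrapolant. Uses the exact piecewise-polynomial
    antiderivative, well inside any 1e-8 relative quadrature tolerance.
    """
    if t0 >= t1:
        raise ValueError("t0 must be < t1")
    lo, hi = fit.span
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError(f"window [{t0}, {t1}] outside observed span [{lo}, {hi}]")
    return float(fit.spline.integrate(t0, t1))


def peak_metrics(series: SeasonSeries) -> tuple[int, float]:
    """(doy, NDVI) of the maximum *observed* value; ties go to the earliest day."""
    if len(series) == 0:
        raise ValueError("empty series")
    i = int(np.argmax(series.ndvi))  # argmax returns first maximum -> earliest day
    return series.doy[i], series.ndvi[i]


def partition_season(
    series: SeasonSeries, mode: str = "median_doy"
) -> tuple[list[tuple[int, float]], list[tuple[int, float]], float]:
    """Split a series into early/late halves; returns (early, late, boundary_doy).

    Modes: ``median_doy`` (boundary at the median observed day), ``median_count``
    (ordered list split at the midpoint index) and ``peak_doy`` (boundary at the
    day of maximum observed NDVI). An observation falling exactly on the
    boundary belongs to both halves, keeping the two integration windows
    contiguous.
    """
    if mode not in PARTITION_MODES:
        raise ValueError(f"unknown partition mode {mode!r}")
    if len(series) < 2:
        raise ValueError("need at least 2 observations to partition")
    obs = list(zip(series.doy, series.ndvi))
    n = len(obs)

    if mode == "median_doy":
        boundary = float(np.median(series.doy))
    elif mode == "peak_doy":
        boundary = float(peak_metrics(series)[0])
    else:  # median_count
        if n % 2 == 1:
            boundary = float(series.doy[n // 2])
        else:
            boundary = 0.5 * (series.doy[n // 2 - 1] + series.doy[n // 2])

    early = [(d, v) for d, v in obs if d <= boundary]
    late = [(d, v) for d, v in obs if d >= boundary]
    return early, late, boundary


@dataclass
class PhaseSlope:
    slope: float
    r2: float
    n: int


def phase_slope(series: SeasonSeries, phase: str, peak_doy: int) -> PhaseSlope | None:
    """OLS slope of NDVI on doy over one phase of the season.

    Green-up uses observations at or before the peak day, senescence at or
    after it (the peak observation anchors both regressions). Returns None if
    the phase has fewer than 3 points; callers record a reason code.
    """
    if phase == "greenup":
        pts = [(d, v) for d, v in zip(series.doy, series.ndvi) if d <= peak_doy]
    elif phase == "senescence":
        pts = [(d, v) for d, v in zip(series.doy, series.ndvi) if d >= peak_doy]
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if len(pts) < 3:
        return None
    x = np.array([d for d, _ in pts], dtype=float)
    y = np.array([v for _, v in pts], dtype=float)
    res = stats.linregress(x, y)
    return PhaseSlope(slope=float(res.slope), r2=float(res.rvalue ** 2), n=len(pts))


METRIC_COLUMNS = [
    "subplot_id", "year", "plot_id", "richness", "treatment",
    "indvi_total", "indvi_early", "indvi_late", "spline_r2",
    "peak_doy", "peak_ndvi", "doy_min", "doy_max",
    "greenup_slope", "greenup_r2", "senescence_slope", "senescence_r2",
    "boundary_doy", "reason_codes",
]


def metrics_table(
    series_list: list[SeasonSeries], partition_mode: str = "median_doy"
) -> pd.DataFrame:
    """One row of phenology metrics per subplot-year series.

    Rows with an uncomputable component (e.g. a phase with < 3 points) carry
    NaN for that metric plus a reason code in ``reason_codes``; nothing is
    silently dropped. All R² values are kept for use as model weights.
    """
    rows = []
    for s in series_list:
        reasons: list[str] = []
        fit = fit_spline(s)
        if fit.constant:
            reasons.append("constant-series")
        _, _, boundary = partition_season(s, mode=partition_mode)
        lo, hi = fit.span
        total = integrate_indvi(fit, lo, hi)
        early = integrate_indvi(fit, lo, boundary)
        late = integrate_indvi(fit, boundary, hi)
        pk_doy, pk_val = peak_metrics(s)

        row = {
            "subplot_id": s.subplot_id, "year": s.year, "plot_id": s.plot_id,
            "richness": s.richness, "treatment": s.treatment,
            "indvi_total": total, "indvi_early": early, "indvi_late": late,
            "spline_r2": fit.r2, "peak_doy": pk_doy, "peak_ndvi": pk_val,
            "doy_min": lo, "doy_max": hi, "boundary_doy": boundary,
        }
        for phase, pfx in (("greenup", "greenup"), ("senescence", "senescence")):
            ps = phase_slope(s, phase, pk_doy)
            if ps is None:
                row[f"{pfx}_slope"] = np.nan
                row[f"{pfx}_r2"] = np.nan
                reasons.append(f"{pfx}-underdetermined")
            else:
                row[f"{pfx}_slope"] = ps.slope
                row[f"{pfx}_r2"] = ps.r2
        row["reason_codes"] = ";".join(reasons)
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def weight_column(metrics: pd.DataFrame, response: str) -> str | None:
    """Name of the fit-quality R² column used to weight a given response."""
    if response in ("indvi_total", "indvi_early", "indvi_late"):
        return "spline_r2"
    if response == "greenup_slope":
        return "greenup_r2"
    if response == "senescence_slope":
        return "senescence_r2"
    return None  # peak_doy and peak_ndvi are unweighted
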
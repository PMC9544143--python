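"""Weighted variance-components linear mixed models.

Fits y = X beta + sum_k Z_k u_k + e by REML or ML, where each u_k is an
i.i.d. random-intercept vector (year, plot, subplot, ... — crossed or nested
factors are all just integer-coded grouping columns), and the residual e has
covariance sigma^2 * R0 with

    R0 = diag(1 / w_i)                         (independent residuals), or
    R0[i, j] = rho^|t_i - t_j| / sqrt(w_i w_j) (AR(1) within a grouping unit).

Case weights w_i scale residual precision, so observations from better-fitting
upstream regressions (higher R^2) carry more weight. The likelihood is
profiled over sigma^2 and the fixed effects; the remaining parameters are the
variance ratios gamma_k = sigma_k^2 / sigma^2 (optimised on the standard-
deviation-ratio scale, where the 0 boundary is an ordinary point) and, when
requested, the AR(1) correlation rho, which may be negative. Marginal
covariance inverses use the Woodbury identity in its sqrt(Gamma) form, so a
variance ratio of exactly zero is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

RHO_BOUND = 0.95
_SINGULAR_TOL = 1e-4  # on the sd-ratio scale


@dataclass
class RandomTerm:
    """A random-intercept factor: integer codes 0..n_levels-1 per observation."""

    name: str
    codes: np.ndarray

    @property
    def n_levels(self) -> int:
        return int(self.codes.max()) + 1 if len(self.codes) else 0


@dataclass
class AR1Spec:
    """AR(1) residual correlation across ``times`` within each ``unit``."""

    unit_codes: np.ndarray   # grouping unit (e.g. subplot), int codes
    times: np.ndarray        # time index (e.g. calendar year), numeric


@dataclass
class LMMResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    variance_components: dict[str, float]   # sigma^2 per term + "residual"
    loglik: float
    method: str
    n: int
    converged: bool
    singular: bool
    rho: float | None = None
    term_names: list[str] = field(default_factory=list)

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _indicator(codes: np.ndarray) -> np.ndarray:
    n, m = len(codes), int(codes.max()) + 1
    Z = np.zeros((n, m))
    Z[np.arange(n), codes] = 1.0
    return Z


def _ar1_blocks(ar1: AR1Spec, w: np.ndarray):
    """Unit blocks grouped by shared lag pattern, so each distinct pattern's
    correlation matrix is factorised once per rho and applied batched."""
    order = np.lexsort((ar1.times, ar1.unit_codes))
    groups: dict[tuple, list[np.ndarray]] = {}
    for u in np.unique(ar1.unit_codes):
        idx = order[ar1.unit_codes[order] == u]
        lags = np.abs(ar1.times[idx][:, None] - ar1.times[idx][None, :])
        groups.setdefault(tuple(lags.ravel()), []).append(idx)
    out = []
    for key, idx_list in groups.items():
        k = len(idx_list[0])
        lags = np.asarray(key, dtype=float).reshape(k, k)
        out.append((np.vstack(idx_list), lags))  # (n_units, k) indices
    return out


class _Workspace:
    """Precomputed pieces of the profiled deviance for one model."""

    def __init__(self, y, X, terms, weights, ar1):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.terms = terms
        self.w = weights
        self.ar1 = ar1
        self.Z = np.hstack([_indicator(t.codes) for t in terms])
        self.sizes = [t.n_levels for t in terms]
        self.m = self.Z.shape[1]
        # B = [X | y | Z]; all quadratic forms come from B' R0^-1 B
        self.B = np.hstack([X, y[:, None], self.Z])
        if ar1 is None:
            R0invB = weights[:, None] * self.B
            self._S0 = self.B.T @ R0invB
            self._logdetR0_0 = -float(np.sum(np.log(weights)))
        else:
            self.blocks = _ar1_blocks(ar1, weights)

    def quad_forms(self, rho: float | None):
        """(S, logdet R0) with S = B' R0^-1 B for the given rho."""
        if self.ar1 is None or rho is None or rho == 0.0:
            if self.ar1 is None:
                return self._S0, self._logdetR0_0
        if rho is None:
            rho = 0.0
        R0invB = np.empty_like(self.B)
        logdet = 0.0
        for idx, lags in self.blocks:   # idx: (n_units, k) row indices
            C = rho ** lags
            Cinv = linalg.inv(C)
            sign, ld = np.linalg.slogdet(C)
            logdet += len(idx) * float(ld)
            logdet -= float(np.sum(np.log(self.w[idx])))
            sw = np.sqrt(self.w[idx])                       # (n_units, k)
            scaled = sw[..., None] * self.B[idx]            # (n_units, k, q)
            # R0 block = D^-1/2 C D^-1/2  =>  inverse = D^1/2 C^-1 D^1/2
            R0invB[idx] = sw[..., None] * np.einsum("ij,bjq->biq", Cinv, scaled)
        return self.B.T @ R0invB, logdet

    def profiled(self, gamma: np.ndarray, rho: float | None, reml: bool):
        """Return (-2 log-lik profiled over beta and sigma^2, components)."""
        S, logdetR0 = self.quad_forms(rho)
        p, m = self.p, self.m
        XtRX = S[:p, :p]
        XtRy = S[:p, p]
        ytRy = S[p, p]
        ZtRX = S[p + 1:, :p]
        ZtRy = S[p + 1:, p]
        A = S[p + 1:, p + 1:]

        ghalf = np.repeat(np.sqrt(gamma), self.sizes)
        M = ghalf[:, None] * A * ghalf[None, :]
        M[np.diag_indices(m)] += 1.0
        cf = linalg.cho_factor(M, lower=True)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

        GZtRX = ghalf[:, None] * ZtRX
        GZtRy = ghalf * ZtRy
        MinvZX = linalg.cho_solve(cf, GZtRX)
        MinvZy = linalg.cho_solve(cf, GZtRy)

        XtVX = XtRX - GZtRX.T @ MinvZX
        XtVy = XtRy - GZtRX.T @ MinvZy
        ytVy = ytRy - GZtRy @ MinvZy

        cfx = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve(cfx, XtVy)
        q = float(ytVy - XtVy @ beta)
        q = max(q, 1e-30)
        logdetXtVX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))

        nstar = self.n - p if reml else self.n
        dev = nstar * (1.0 + np.log(2.0 * np.pi * q / nstar)) + logdetM + logdetR0
        if reml:
            dev += logdetXtVX
        sigma2 = q / nstar
        cov_beta = sigma2 * linalg.cho_solve(cfx, np.eye(p))
        return dev, beta, cov_beta, sigma2


def fit_lmm_engine(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    weights: np.ndarray | None = None,
    method: str = "reml",
    ar1: AR1Spec | None = None,
    estimate_rho: bool = False,
) -> LMMResult:
    """Fit the weighted variance-components model.

    Parameters
    ----------
    y, X
        Response and fixed-effects design (full column rank).
    terms
        Random-intercept factors.
    weights
        Positive case weights; residual variance of case i is sigma^2 / w_i.
    method
        "reml" (reported fits) or "ml" (likelihood-ratio comparisons).
    ar1, estimate_rho
        With ``estimate_rho`` the AR(1) correlation is estimated in
        (-0.95, 0.95); otherwise residuals are independent given the
        random effects.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("case weights must be > 0")
    reml = method.lower() == "reml"
    if method.lower() not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")

    # degenerate data: y exactly in the column span of X -> all variances 0
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    scale = max(float(np.mean(y**2)), 1e-30)
    if float(np.mean(resid**2)) < 1e-24 * scale:
        vc = {t.name: 0.0 for t in terms}
        vc["residual"] = 0.0
        return LMMResult(beta=beta_ols, cov_beta=np.zeros((p, p)),
                         variance_components=vc, loglik=np.inf, method=method,
                         n=n, converged=True, singular=True,
                         rho=0.0 if estimate_rho else None,
                         term_names=[t.name for t in terms])

    if estimate_rho and ar1 is None:
        raise ValueError("estimate_rho requires an AR1Spec")
    ws = _Workspace(y, X, terms, weights, ar1 if estimate_rho else None)
    k = len(terms)

    def unpack(params):
        gamma = params[:k] ** 2
        rho = None
        if estimate_rho:
            rho = float(np.clip(params[k], -RHO_BOUND + 1e-6, RHO_BOUND - 1e-6))
        return gamma, rho

    def objective(params):
        gamma, rho = unpack(params)
        try:
            return ws.profiled(gamma, rho, reml)[0]
        except linalg.LinAlgError:
            return 1e12

    x0 = np.concatenate([np.full(k, 1.0), [0.0] if estimate_rho else []])
    bounds = [(0.0, None)] * k + ([(-RHO_BOUND, RHO_BOUND)] if estimate_rho else [])
    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    # polish with a derivative-free pass; robust near the gamma = 0 boundary
    res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-9,
                                      "maxiter": 400})
    best = res2 if res2.fun <= res.fun else res

    gamma, rho = unpack(best.x)
    dev, beta, cov_beta, sigma2 = ws.profiled(gamma, rho, reml)
    vc = {t.name: float(g * sigma2) for t, g in zip(terms, gamma)}
    vc["residual"] = float(sigma2)
    return LMMResult(
        beta=beta, cov_beta=cov_beta, variance_components=vc,
        loglik=-0.5 * float(dev), method=method, n=n,
        converged=bool(res.success or res2.success),
        singular=bool(np.any(np.abs(best.x[:k]) < _SINGULAR_TOL)),
        rho=rho, term_names=[t.name for t in terms],
    )
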
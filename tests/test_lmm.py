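"""Variance-components engine against independent mixed-model software."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from greenwave.inference import simulate_lmm_dataset
from greenwave.lmm import AR1Spec, RandomTerm, fit_lmm_engine


def design_pieces(df, factors=("treatment",)):
    X = pd.get_dummies(df[list(factors)].astype(str).agg("|".join, axis=1)) \
        .to_numpy(float)
    terms = [RandomTerm(c, pd.Categorical(df[c]).codes.astype(int))
             for c in ("year", "plot_id", "subplot_id")]
    return X, terms


@pytest.fixture(scope="module")
def dataset():
    df = simulate_lmm_dataset(n_plots=8, treatments=3, n_years=4,
                              sd_year=0.4, sd_plot=0.6, sd_subplot=0.3,
                              sd_resid=0.9, seed=13)
    df["w"] = np.random.default_rng(5).uniform(0.3, 1.0, len(df))
    return df


class TestAgainstStatsmodels:
    def test_single_grouping_reml_matches_mixedlm(self):
        import statsmodels.formula.api as smf

        df = simulate_lmm_dataset(n_plots=10, treatments=3, n_years=4,
                                  sd_year=0, sd_subplot=0, sd_plot=0.7,
                                  sd_resid=1.0, seed=3)
        y = df["value"].to_numpy()
        X = pd.get_dummies(df["treatment"]).to_numpy(float)
        terms = [RandomTerm("plot",
                            pd.Categorical(df["plot_id"]).codes.astype(int))]
        ours = fit_lmm_engine(y, X, terms, method="reml")
        ref = smf.mixedlm("value ~ 0 + treatment", df,
                          groups=df["plot_id"]).fit(reml=True)
        assert np.allclose(ours.beta, ref.fe_params.values, atol=1e-5)
        assert np.allclose(ours.se_beta, ref.bse_fe.values, atol=1e-5)
        assert ours.variance_components["plot"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert ours.variance_components["residual"] == pytest.approx(
            ref.scale, rel=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)


class TestAgainstRLme4:
    def test_weighted_crossed_fit_matches_lmer(self, dataset, tmp_path):
        """Weighted three-factor fit checked against lme4::lmer, which uses
        the same case-weight convention (residual variance sigma^2 / w)."""
        df = dataset
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$cell <- d$treatment
            m <- lmer(value ~ 0 + cell + (1|year) + (1|plot_id) + (1|subplot_id),
                      data = d, weights = w, REML = TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(paste(fe, collapse=","), "\n")
            cat(paste(sqrt(diag(as.matrix(vcov(m)))), collapse=","), "\n")
            cat(paste(vc$vcov, collapse=","), "\n")
        """))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        fe = np.array([float(v) for v in lines[0].split(",")])
        se = np.array([float(v) for v in lines[1].split(",")])
        vc = np.array([float(v) for v in lines[2].split(",")])

        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        ours = fit_lmm_engine(y, X, terms, weights=df["w"].to_numpy(),
                              method="reml")
        assert np.allclose(ours.beta, fe, atol=1e-4)
        assert np.allclose(ours.se_beta, se, rtol=1e-3)
        # lme4 orders VarCorr as listed: subplot_id, plot_id, year, residual
        ours_vc = ours.variance_components
        ref_named = dict(zip(["subplot_id", "plot_id", "year", "residual"], vc))
        for name_r, name_o in [("subplot_id", "subplot_id"),
                               ("plot_id", "plot_id"), ("year", "year"),
                               ("residual", "residual")]:
            assert ours_vc[name_o] == pytest.approx(
                ref_named[name_r], rel=5e-3, abs=1e-4)


class TestEngineProperties:
    def test_weight_rescaling_invariance(self, dataset):
        df = dataset
        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        w = df["w"].to_numpy()
        a = fit_lmm_engine(y, X, terms, weights=w)
        b = fit_lmm_engine(y, X, terms, weights=2.0 * w)
        assert np.allclose(a.beta, b.beta, atol=1e-6)
        assert np.allclose(a.se_beta, b.se_beta, rtol=1e-4)

    def test_uniform_weights_match_unweighted(self, dataset):
        df = dataset
        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        a = fit_lmm_engine(y, X, terms, weights=np.full(len(df), 3.0))
        b = fit_lmm_engine(y, X, terms)
        assert np.allclose(a.beta, b.beta, atol=1e-6)
        assert np.allclose(a.se_beta, b.se_beta, rtol=1e-4)

    def test_degenerate_zero_variance_data(self):
        df = simulate_lmm_dataset(n_plots=4, treatments=3, n_years=3,
                                  sd_year=0, sd_plot=0, sd_subplot=0,
                                  sd_resid=0, cell_means=5.0, seed=0)
        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        res = fit_lmm_engine(y, X, terms)
        assert res.singular
        assert np.allclose(res.beta, 5.0, atol=1e-10)
        assert all(v == 0.0 for v in res.variance_components.values())

    def test_plot_variance_recovery(self):
        """Median relative error of the plot variance component across seeds
        stays within 50% at the 33-plot design size."""
        errs = []
        for seed in range(20):
            df = simulate_lmm_dataset(n_plots=33, treatments=5, n_years=5,
                                      sd_year=0.1, sd_plot=0.2,
                                      sd_subplot=0.1, sd_resid=0.1,
                                      seed=1000 + seed)
            y = df["value"].to_numpy()
            X, terms = design_pieces(df)
            res = fit_lmm_engine(y, X, terms)
            errs.append(abs(res.variance_components["plot_id"] - 0.04) / 0.04)
        assert np.median(errs) < 0.5

    def test_ml_vs_reml_loglik_ordering(self, dataset):
        df = dataset
        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        ml = fit_lmm_engine(y, X, terms, method="ml")
        reml = fit_lmm_engine(y, X, terms, method="reml")
        assert ml.method == "ml" and reml.method == "reml"
        assert np.isfinite(ml.loglik) and np.isfinite(reml.loglik)

    def test_ar1_nested_likelihood_not_lower(self, dataset):
        df = dataset
        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        base = fit_lmm_engine(y, X, terms, method="ml")
        ar1 = AR1Spec(
            unit_codes=pd.Categorical(df["subplot_id"]).codes.astype(int),
            times=df["year"].to_numpy(float))
        full = fit_lmm_engine(y, X, terms, method="ml", ar1=ar1,
                              estimate_rho=True)
        assert full.loglik >= base.loglik - 1e-6

    def test_strong_ar1_detected(self):
        df = simulate_lmm_dataset(n_plots=12, treatments=5, n_years=8,
                                  rho=0.8, sd_resid=1.0, seed=5)
        y = df["value"].to_numpy()
        X, terms = design_pieces(df)
        ar1 = AR1Spec(
            unit_codes=pd.Categorical(df["subplot_id"]).codes.astype(int),
            times=df["year"].to_numpy(float))
        full = fit_lmm_engine(y, X, terms, method="ml", ar1=ar1,
                              estimate_rho=True)
        assert full.rho == pytest.approx(0.8, abs=0.15)
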
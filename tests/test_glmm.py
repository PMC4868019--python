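"""Binomial mixed-model estimation and the model-comparison toolkit.

The Laplace fit is verified three ways: against closed-form GLM results in
degenerate cases, against the package's own adaptive Gauss-Hermite
quadrature, and against an independent reference implementation (R lme4)
on a small fixture.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest

from gullforage.glmm import (GlmmSpec, SpecificationError, aicc, build_design,
                             drop_term_lrt, fit_glmm, kappa_collinearity,
                             parse_formula, r2_nakagawa, rank_models,
                             standardize)


def _sim(seed, n_groups=10, per=30, beta=(-0.3, 0.8), sigma=1.2,
         trials=(5, 20)):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    b = rng.normal(0, sigma, size=n_groups)
    eta = beta[0] + beta[1] * x + b[g]
    n = rng.integers(trials[0], trials[1], size=len(g))
    k = rng.binomial(n, expit(eta))
    return pd.DataFrame({"k": k, "n": n, "x": x,
                         "g": [f"g{i:02d}" for i in g]})


class TestParseFormula:
    def test_binomial_counts_with_single_intercept(self):
        s = parse_formula("n_land/n_forage_points ~ cloud + temp + (1|ind)")
        assert s.response == "n_land" and s.trials == "n_forage_points"
        assert s.fixed == ["cloud", "temp"] and s.random == ("ind",)

    def test_nested_grouping(self):
        s = parse_formula("present ~ veg + (1|transect/field)")
        assert s.random == ("transect", "field")

    def test_star_expands_to_mains_plus_interaction(self):
        s = parse_formula("k/n ~ temp*stage + (1|g)")
        assert s.fixed == ["temp", "stage", "temp:stage"]

    def test_interaction_without_mains_rejected(self):
        with pytest.raises(SpecificationError):
            parse_formula("k/n ~ a:b + (1|g)")

    def test_intercept_only(self):
        s = parse_formula("k/n ~ 1 + (1|g)")
        assert s.fixed == []


class TestFitGlmm:
    def test_pooled_intercept_only_closed_form(self):
        # no random term, sigma^2 fixed 0: MLE intercept = log(k/(n-k))
        df = pd.DataFrame({"k": [30], "n": [100]})
        fit = fit_glmm(df, GlmmSpec("k", "n", [], ()))
        assert fit.beta["(Intercept)"] == pytest.approx(
            np.log(30 / 70), abs=1e-6)

    def test_laplace_close_to_quadrature_small_groups(self):
        df = _sim(11, n_groups=3, per=10)
        fit = fit_glmm(df, "k/n ~ x + (1|g)")
        assert abs(fit.loglik - fit.loglik_agq(15)) <= 0.1
        # quadrature itself converged in node count
        assert fit.loglik_agq(15) == pytest.approx(fit.loglik_agq(25),
                                                   abs=1e-6)

    @pytest.mark.parametrize("n_groups", [10, 50])
    def test_laplace_close_to_quadrature(self, n_groups):
        df = _sim(n_groups, n_groups=n_groups, per=12)
        fit = fit_glmm(df, "k/n ~ x + (1|g)")
        assert abs(fit.loglik - fit.loglik_agq(15)) <= 0.1

    def test_matches_lme4_reference(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = _sim(7)
        df.to_csv(tmp_path / "d.csv", index=False)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{tmp_path}/d.csv");'
            'm <- glmer(cbind(k, n-k) ~ x + (1|g), data=d, family=binomial);'
            'cat(logLik(m), fixef(m), unlist(VarCorr(m)), sep=",")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        ll, b0, b1, s2 = map(float, out.stdout.strip().split(","))
        fit = fit_glmm(df, "k/n ~ x + (1|g)")
        assert fit.loglik == pytest.approx(ll, abs=0.01)
        assert fit.beta["(Intercept)"] == pytest.approx(b0, abs=0.01)
        assert fit.beta["x"] == pytest.approx(b1, abs=0.01)
        assert fit.var_components["g"] == pytest.approx(s2, abs=0.02)

    def test_null_variance_recovered_near_zero(self):
        df = _sim(5, n_groups=20, per=50, sigma=0.0)
        fit = fit_glmm(df, "k/n ~ x + (1|g)")
        assert fit.var_components["g"] < 0.05

    def test_adding_predictor_never_decreases_loglik(self):
        df = _sim(9)
        df["z"] = np.random.default_rng(1).normal(size=len(df))
        base = fit_glmm(df, "k/n ~ x + (1|g)")
        bigger = fit_glmm(df, "k/n ~ x + z + (1|g)")
        assert bigger.loglik >= base.loglik - 1e-6

    def test_beta_recovery_within_wald_intervals(self):
        """True coefficients inside the 95 % Wald CI in >= 90 % of fits."""
        true = {"(Intercept)": -0.3, "x": 0.8}
        hits = {k: 0 for k in true}
        n_rep = 100
        for rep in range(n_rep):
            df = _sim(1000 + rep, n_groups=19, per=53, sigma=2.0)
            fit = fit_glmm(df, "k/n ~ x + (1|g)")
            se = fit.wald_se()
            for name, val in true.items():
                lo = fit.beta[name] - 1.96 * se[name]
                hi = fit.beta[name] + 1.96 * se[name]
                hits[name] += lo <= val <= hi
        for name, h in hits.items():
            assert h >= 90, f"{name}: {h}/100"

    def test_rank_deficient_design_names_alias(self):
        df = _sim(3)
        df["x2"] = df["x"]
        with pytest.raises(SpecificationError, match="x2"):
            fit_glmm(df, "k/n ~ x + x2 + (1|g)")

    def test_single_level_grouping_rejected(self):
        df = _sim(3)
        df["g"] = "only"
        with pytest.raises(SpecificationError):
            fit_glmm(df, "k/n ~ x + (1|g)")


class TestNestedGrouping:
    def _field_like(self, seed, s_out=0.0, s_in=1.0):
        rng = np.random.default_rng(seed)
        rows = []
        u = rng.normal(0, s_out, size=10)
        v = rng.normal(0, s_in, size=50)
        for t in range(10):
            for f in range(5):
                fid = t * 5 + f
                for _ in range(6):
                    x = rng.normal()
                    p = expit(-0.5 + 0.7 * x + u[t] + v[fid])
                    rows.append({"y": int(rng.random() < p), "x": x,
                                 "tr": f"T{t}", "fl": f"F{fid}"})
        return pd.DataFrame(rows)

    def test_zero_outer_variance_estimated_near_zero(self):
        df = self._field_like(2, s_out=0.0, s_in=1.0)
        fit = fit_glmm(df, "y ~ x + (1|tr/fl)")
        assert fit.var_components["tr"] < 0.05

    def test_both_components_recovered_at_scale(self):
        # pool 10 replicates of the design: generative (0.5^2, 1^2)
        est_out, est_in = [], []
        for rep in range(10):
            df = self._field_like(100 + rep, s_out=0.5, s_in=1.0)
            fit = fit_glmm(df, "y ~ x + (1|tr/fl)")
            est_out.append(fit.var_components["tr"])
            est_in.append(fit.var_components["fl"])
        assert np.mean(est_out) == pytest.approx(0.25, abs=0.25)
        assert np.mean(est_in) == pytest.approx(1.0, abs=0.5)


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-100.0, 5, 10**6) == pytest.approx(210.0, abs=1e-4)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)

    def test_uninformative_predictor_raises_median_aicc(self):
        deltas = []
        for rep in range(100):
            df = _sim(2000 + rep, n_groups=8, per=15)
            rng = np.random.default_rng(rep)
            df["noise"] = rng.normal(size=len(df))
            a = fit_glmm(df, "k/n ~ x + (1|g)").aicc
            b = fit_glmm(df, "k/n ~ x + noise + (1|g)").aicc
            deltas.append(b - a)
        assert np.median(deltas) > 0


class TestRankModels:
    def test_best_model_delta_zero_and_order_invariance(self):
        df = _sim(4)
        f1 = fit_glmm(df, "k/n ~ x + (1|g)")
        f0 = fit_glmm(df, "k/n ~ 1 + (1|g)")
        tab = rank_models({"full": f1, "null": f0})
        assert tab["dAICc"].iloc[0] == 0.0
        tab2 = rank_models({"null": f0, "full": f1})
        pd.testing.assert_frame_equal(tab, tab2)

    def test_identical_fits_share_delta(self):
        df = _sim(4)
        f = fit_glmm(df, "k/n ~ x + (1|g)")
        tab = rank_models({"a": f, "b": f})
        assert (tab["dAICc"] == 0.0).all()


class TestR2:
    def test_no_random_variance_makes_marginal_equal_conditional(self):
        df = _sim(5, sigma=0.0, n_groups=20, per=40)
        fit = fit_glmm(df, "k/n ~ x + (1|g)")
        m, c = r2_nakagawa(fit)
        assert m <= c <= 1.0
        assert c == pytest.approx(m, abs=0.02)

    def test_intercept_only_marginal_zero(self):
        df = _sim(6)
        fit = fit_glmm(df, "k/n ~ 1 + (1|g)")
        m, _ = r2_nakagawa(fit)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_conditional_recovered_with_known_components(self):
        # strong known variance shares at n = 1000 rows; 50 groups keep the
        # chi-square noise of the realised intercept variance small
        rng = np.random.default_rng(8)
        g = np.repeat(np.arange(50), 20)
        x = rng.normal(size=1000)
        b = rng.normal(0, 1.5, size=50)
        eta = 1.0 * x + b[g]
        n = np.full(1000, 15)
        k = rng.binomial(n, expit(eta))
        df = pd.DataFrame({"k": k, "n": n, "x": x, "g": g.astype(str)})
        fit = fit_glmm(df, "k/n ~ x + (1|g)")
        _, c = r2_nakagawa(fit)
        truth = (1.0 + 1.5**2) / (1.0 + 1.5**2 + np.pi**2 / 3)
        assert c == pytest.approx(truth, abs=0.08)


class TestStandardize:
    def test_numeric_scaled_to_half_sd(self):
        df = pd.DataFrame({"k": [1, 2, 3, 4], "n": [5] * 4,
                           "x": [1.0, 2.0, 4.0, 9.0], "g": list("abab")})
        out, mapping = standardize(df, "k/n ~ x + (1|g)")
        assert out["x"].std(ddof=1) == pytest.approx(0.5)
        assert out["x"].mean() == pytest.approx(0.0)
        center, scale = mapping["x"]
        assert scale == pytest.approx(2 * df["x"].std(ddof=1))

    def test_sd_half_predictor_keeps_scale(self):
        x = np.array([0.0, 1.0] * 8) * 0.5 + np.linspace(0, 0.01, 16)
        x = (x - x.mean()) / x.std(ddof=1) * 0.5  # construct SD exactly 0.5
        df = pd.DataFrame({"k": [1] * 16, "n": [5] * 16, "x": x})
        out, mapping = standardize(df, GlmmSpec("k", "n", ["x"], ()))
        assert mapping["x"][1] == pytest.approx(1.0)
        np.testing.assert_allclose(out["x"], x - x.mean(), atol=1e-12)

    def test_binary_centred_only(self):
        df = pd.DataFrame({"k": [1] * 4, "n": [5] * 4,
                           "x": [0.0, 0.0, 0.0, 1.0]})
        out, _ = standardize(df, GlmmSpec("k", "n", ["x"], ()))
        assert sorted(set(np.round(out["x"], 6))) == [-0.25, 0.75]

    def test_zero_variance_predictor_named(self):
        df = pd.DataFrame({"k": [1] * 4, "n": [5] * 4, "x": [2.0] * 4})
        with pytest.raises(SpecificationError, match="x"):
            standardize(df, GlmmSpec("k", "n", ["x"], ()))


class TestKappa:
    def test_orthonormal_design_gives_one(self):
        # orthogonal columns of equal norm after including the intercept
        n = 8
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        df = pd.DataFrame({"k": [1] * n, "n": [5] * n, "x1": x1, "x2": x2})
        fit = fit_glmm(df, GlmmSpec("k", "n", ["x1", "x2"], ()))
        assert kappa_collinearity(fit) == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"k": [1] * 40, "n": [5] * 40,
                           "a": rng.normal(size=40), "b": rng.normal(size=40)})
        fit = fit_glmm(df, GlmmSpec("k", "n", ["a", "b"], ()))
        X, _ = build_design(df, ["a", "b"])
        sv = np.linalg.svd(X, compute_uv=False)
        assert fit.kappa == pytest.approx(sv[0] / sv[-1], abs=1e-8)


class TestDropTermLrt:
    def test_chi2_nonnegative_and_df_counts_dummies(self):
        rng = np.random.default_rng(3)
        df = _sim(3, n_groups=8, per=40)
        df["season"] = pd.Categorical(rng.choice(list("wxyz"), size=len(df)))
        fit = fit_glmm(df, "k/n ~ x + season + (1|g)")
        tab = drop_term_lrt(fit, df).set_index("term")
        assert (tab["chi2"] >= 0).all()
        assert tab.loc["season", "df"] == 3

    def test_marginality_protects_mains_under_interaction(self):
        df = _sim(3, n_groups=8, per=30)
        rng = np.random.default_rng(4)
        df["w"] = rng.normal(size=len(df))
        fit = fit_glmm(df, "k/n ~ x*w + (1|g)")
        dropped = set(drop_term_lrt(fit, df)["term"])
        assert dropped == {"x:w"}

    def test_null_term_p_values_roughly_uniform(self):
        """Type-I calibration: p for a truly null term ~ U(0,1)."""
        ps = []
        for rep in range(200):
            df = _sim(3000 + rep, n_groups=8, per=15, beta=(-0.3, 0.0))
            fit = fit_glmm(df, "k/n ~ x + (1|g)")
            tab = drop_term_lrt(fit, df)
            ps.append(float(tab.loc[tab["term"] == "x", "p"].iloc[0]))
        assert kstest(ps, "uniform").pvalue > 0.01
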
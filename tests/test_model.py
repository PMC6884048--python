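"""GLM core: IRLS correctness, penalization, penalty selection, inference."""

import math
import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from oxydose import (
    ModelDefinition,
    SeparationError,
    build_design,
    fit_glm,
    fit_penalized,
    lr_test,
    select_penalty,
    term_odds_ratio,
)


def logistic_data(rng, n=500, p=3, beta=None, intercept=-1.0):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    b = np.concatenate([[intercept], beta if beta is not None else rng.normal(0, 0.5, p)])
    mu = 1 / (1 + np.exp(-(X @ b)))
    y = rng.random(n) < mu
    return X, y.astype(float), b


class TestFitGlm:
    def test_intercept_only_balanced(self):
        y = np.array([0.0, 1.0] * 25)
        fit = fit_glm(np.ones((50, 1)), y)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.predict(np.ones((1, 1)))[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("link", ["logit", "probit", "cloglog"])
    def test_matches_statsmodels(self, link, rng):
        # independent optimizer oracle on 20 random small datasets
        families = {
            "logit": sm.families.Binomial(sm.families.links.Logit()),
            "probit": sm.families.Binomial(sm.families.links.Probit()),
            "cloglog": sm.families.Binomial(sm.families.links.CLogLog()),
        }
        n_checks = 20 if link == "logit" else 5
        for _ in range(n_checks):
            X, y, _ = logistic_data(rng, n=300, p=3)
            ours = fit_glm(X, y, link=link)
            ref = sm.GLM(y, X, family=families[link]).fit()
            assert np.allclose(ours.params, ref.params, atol=1e-6)
            assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
            assert np.allclose(
                np.sqrt(np.diag(ours.cov)), ref.bse, rtol=1e-3
            )

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(7)
        n = 50_000
        x = (rng.random(n) < 0.5).astype(float)
        beta = np.array([-2.0, math.log(1.5)])
        mu = 1 / (1 + np.exp(-(beta[0] + beta[1] * x)))
        y = (rng.random(n) < mu).astype(float)
        fit = fit_glm(np.column_stack([np.ones(n), x]), y)
        se = math.sqrt(fit.cov[1, 1])
        assert abs(fit.params[1] - beta[1]) < 1.96 * se

    def test_perfect_separation_raises(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_glm(np.column_stack([np.ones(40), x]), y)

    def test_aic_identity_and_monotone_loglik(self, rng):
        X, y, _ = logistic_data(rng, n=400, p=4)
        reduced = fit_glm(X[:, :3], y)
        full = fit_glm(X, y)
        assert full.log_likelihood >= reduced.log_likelihood - 1e-10
        for f in (reduced, full):
            assert f.aic == pytest.approx(
                -2 * f.log_likelihood + 2 * f.effective_df
            )


class TestPenalized:
    def make(self, rng, n=2000):
        X, y, _ = logistic_data(rng, n=n, p=4)
        mask = np.array([False, False, False, True, True])
        return X, y, mask

    def test_lambda_zero_equals_mle(self, rng):
        X, y, mask = self.make(rng)
        a = fit_glm(X, y)
        b = fit_penalized(X, y, lam=0.0, penalized_mask=mask)
        assert np.allclose(a.params, b.params, atol=1e-6)

    def test_infinite_shrinkage_limit(self, rng):
        X, y, mask = self.make(rng)
        fit = fit_penalized(X, y, lam=1e9, penalized_mask=mask)
        assert np.all(np.abs(fit.params[mask]) < 1e-4)
        assert fit.effective_df == pytest.approx((~mask).sum(), abs=1e-3)

    def test_effective_df_matches_eigendecomposition_oracle(self, rng):
        X, y, mask = self.make(rng)
        lam = 3.0
        fit = fit_penalized(X, y, lam=lam, penalized_mask=mask)
        # independent linear-algebra route: raw-scale information and the
        # equivalent raw-scale penalty lam * sd_j^2 (a unit penalty on the
        # standardized coefficient sd_j * beta_j)
        mu = fit.predict(X)
        w = mu * (1 - mu)
        H = (X.T * w) @ X
        P = np.zeros(X.shape[1])
        P[mask] = lam * X[:, mask].std(axis=0) ** 2
        M = np.linalg.solve(H + np.diag(P), H)
        edf_eigen = float(np.sum(np.linalg.eigvals(M).real))
        assert fit.effective_df == pytest.approx(edf_eigen, abs=1e-8)
        assert fit.effective_df <= X.shape[1]

    def test_penalized_df_between_bounds(self, rng):
        X, y, mask = self.make(rng)
        fit = fit_penalized(X, y, lam=5.0, penalized_mask=mask)
        assert (~mask).sum() < fit.effective_df < X.shape[1]


class TestSelectPenalty:
    def test_single_value_grid(self, rng):
        X, y, mask = TestPenalized().make(rng)
        lam, fit = select_penalty(X, y, penalized_mask=mask, lambda_grid=[2.0])
        assert lam == 2.0 and fit.lam == 2.0

    def test_aic_recomputes_from_parts(self, rng):
        X, y, mask = TestPenalized().make(rng)
        lam, fit = select_penalty(
            X, y, penalized_mask=mask, lambda_grid=[0.0, 1.0, 8.0]
        )
        assert fit.aic == pytest.approx(
            -2 * fit.log_likelihood + 2 * fit.effective_df
        )

    def test_null_interactions_favor_shrinkage(self):
        # when the penalized columns carry no signal, AIC should usually
        # prefer some shrinkage over the unpenalized fit
        hits = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            n = 4000
            X = np.column_stack(
                [np.ones(n), rng.normal(size=(n, 2)), rng.normal(size=(n, 2))]
            )
            beta = np.array([-1.5, 0.4, -0.3, 0.0, 0.0])
            mu = 1 / (1 + np.exp(-(X @ beta)))
            y = (rng.random(n) < mu).astype(float)
            mask = np.array([False, False, False, True, True])
            lam, _ = select_penalty(X, y, penalized_mask=mask)
            hits += lam > 0
        assert hits >= 0.6 * reps


class TestInference:
    def test_lr_identical_models(self, rng):
        X, y, _ = logistic_data(rng, n=300, p=2)
        fit = fit_glm(X, y)
        chi2, df, p = lr_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_lr_printed_example(self):
        from scipy.stats import chi2 as chi2_dist

        assert round(float(chi2_dist.sf(5.815, 1)), 3) == 0.016

    def test_lr_requires_nesting(self, rng):
        import pandas as pd

        X, y, _ = logistic_data(rng, n=300, p=3)
        cols = ["intercept", "a", "b", "c"]
        df = pd.DataFrame(X, columns=cols)
        a = fit_glm(df[["intercept", "a"]], y)
        b = fit_glm(df[["intercept", "b", "c"]], y)
        with pytest.raises(Exception):
            lr_test(a, b)

    def test_or_null_coefficient(self):
        y = np.array([0.0, 1.0] * 50)
        x = np.array([0.0, 0.0, 1.0, 1.0] * 25)
        fit = fit_glm(np.column_stack([np.ones(100), x]), y)
        out = term_odds_ratio(fit, "x1")
        assert out["ci_low"] < 1.0 < out["ci_high"]

    def test_or_matches_published_interval_arithmetic(self):
        # beta = ln(1.74) with SE chosen so the Wald chi-square is 5.815
        beta = math.log(1.74)
        se = beta / math.sqrt(5.815)
        lo = math.exp(beta - 1.959964 * se)
        assert round(lo, 2) == 1.11

    def test_exp_identity(self):
        assert math.exp(0.405465) == pytest.approx(1.5, abs=1e-5)

    def test_spline_term_rejected(self, nested_subsets):
        _, _, subsets = nested_subsets
        t = subsets[0].table
        fit = fit_glm(build_design(t), t["icu_death"].to_numpy(float))
        with pytest.raises(ValueError, match="spline"):
            term_odds_ratio(fit, "age_years")


class TestDesignGuards:
    def test_constant_indicator_dropped_with_warning(self, nested_subsets):
        _, _, subsets = nested_subsets
        t = subsets[0].table.copy()
        t["any_exposure"] = 1.0
        with pytest.warns(UserWarning, match="any_exposure"):
            d = build_design(t)
        assert "any_exposure" not in d.names and "dose_kpa" in d.names
        fit = fit_glm(d, t["icu_death"].to_numpy(float))
        assert fit.converged

    def test_link_robustness_sign_agreement(self, nested_subsets):
        # positive any-exposure effect keeps its sign across link functions
        _, _, subsets = nested_subsets
        t = subsets[0].table
        y = t["icu_death"].to_numpy(float)
        d = build_design(t)
        signs = [
            np.sign(fit_penalized(d, y, link=link).coef("any_exposure"))
            for link in ("logit", "probit", "cloglog")
        ]
        assert len(set(signs)) == 1
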
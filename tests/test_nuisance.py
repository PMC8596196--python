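"""Adaptive LASSO behaviour (null sparsity, oracle selection, plain-LASSO
reduction), propensity truncation, and outcome-model closed forms."""

import numpy as np
import pytest
from scipy.special import expit

from msdr.nuisance import (
    AdaptiveLassoFit,
    _l1_logistic,
    fit_adaptive_lasso_logistic,
    fit_outcome_models,
    newton_cloglog,
    newton_logistic,
    predict_cloglog,
    predict_propensity,
)


def _bernoulli(rng, p):
    return (rng.random(len(p)) < p).astype(float)


class TestAdaptiveLasso:
    def test_pure_noise_selection_is_sparse(self):
        """Null design (n=500, p=50): the CV-selected model is empty in the
        majority of replicates and never retains more than a handful of
        noise features (rates cross-checked against glmnet's adaptive
        cv.glmnet with lambda.1se, which behaves identically)."""
        nnz = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(500, 50))
            y = (rng.random(500) < 0.4).astype(float)
            fit = fit_adaptive_lasso_logistic(X, y, seed=seed)
            nnz.append(int(np.count_nonzero(fit.coef)))
        assert sum(n == 0 for n in nnz) >= 6
        assert np.median(nnz) == 0
        assert np.mean(nnz) <= 3

    def test_single_strong_predictor_oracle_selection(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(1000, 10))
            y = _bernoulli(rng, expit(2.0 * X[:, 0]))
            fit = fit_adaptive_lasso_logistic(X, y, seed=seed)
            hits += int(fit.coef[0] != 0 and np.all(fit.coef[1:] == 0))
        assert hits >= 9

    def test_gamma_zero_reduces_to_plain_lasso(self, rng):
        X = rng.normal(size=(400, 8))
        y = _bernoulli(rng, expit(X[:, 0] - 0.5 * X[:, 3]))
        fit = fit_adaptive_lasso_logistic(X, y, gamma=0.0, seed=1)
        # plain L1 fit at the same penalty on the internally-standardized X
        mean, sd = X.mean(0), X.std(0)
        Xs = (X - mean) / sd
        b0, beta = _l1_logistic(Xs, y, fit.lam)
        coef = beta / sd
        assert np.allclose(fit.coef, coef, atol=1e-6)
        assert fit.intercept == pytest.approx(b0 - mean @ coef, abs=1e-6)

    def test_constant_column_gets_zero_coefficient(self, rng):
        X = rng.normal(size=(300, 4))
        X[:, 2] = 3.7
        y = _bernoulli(rng, expit(X[:, 0]))
        fit = fit_adaptive_lasso_logistic(X, y, seed=2)
        assert fit.coef[2] == 0.0

    def test_degenerate_outcome_constant_model(self, rng):
        X = rng.normal(size=(100, 3))
        with pytest.warns(UserWarning):
            fit = fit_adaptive_lasso_logistic(X, np.ones(100), seed=0)
        assert np.all(fit.coef == 0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(300, 6))
        y = _bernoulli(rng, expit(X[:, 1]))
        f1 = fit_adaptive_lasso_logistic(X, y, seed=9)
        f2 = fit_adaptive_lasso_logistic(X, y, seed=9)
        assert np.array_equal(f1.coef, f2.coef) and f1.lam == f2.lam

    def test_prediction_invariant_to_column_rescaling(self, rng):
        X = rng.normal(size=(500, 5))
        y = _bernoulli(rng, expit(X[:, 0]))
        f1 = fit_adaptive_lasso_logistic(X, y, seed=4)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        f2 = fit_adaptive_lasso_logistic(X2, y, seed=4)
        assert np.allclose(f1.predict_proba(X), f2.predict_proba(X2), atol=1e-6)

    def test_sparsity_monotone_along_penalty_grid(self, rng):
        X = rng.normal(size=(400, 12))
        y = _bernoulli(rng, expit(X[:, 0] + 0.5 * X[:, 1]))
        Xs = (X - X.mean(0)) / X.std(0)
        lams = np.logspace(-0.5, -3, 10) * 0.5
        nnz = [np.sum(_l1_logistic(Xs, y, lam)[1] != 0) for lam in lams]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))


class TestPropensity:
    def test_null_model_gives_half(self):
        fit = AdaptiveLassoFit(0.0, np.zeros(3), 0.1, np.ones(3), 1.0, 5, 0)
        assert np.all(predict_propensity(fit, np.random.randn(10, 3)) == 0.5)

    def test_truncation_bounds(self):
        fit = AdaptiveLassoFit(-10.0, np.zeros(1), 0.1, np.ones(1), 1.0, 5, 0)
        assert np.all(predict_propensity(fit, np.zeros((5, 1))) == 0.01)
        fit.intercept = 10.0
        assert np.all(predict_propensity(fit, np.zeros((5, 1))) == 0.99)

    def test_inverse_link_hand_computation(self):
        # 3 patients, eta = 0.5 + 1*x1 - 2*x2
        fit = AdaptiveLassoFit(0.5, np.array([1.0, -2.0]), 0.1, np.ones(2), 1.0, 5, 0)
        X = np.array([[0.0, 0.0], [1.0, 0.5], [-1.0, 1.0]])
        expected = 1 / (1 + np.exp(-(0.5 + X[:, 0] - 2 * X[:, 1])))
        assert np.allclose(predict_propensity(fit, X), expected, atol=1e-12)


class TestOutcomeModels:
    def test_null_binary_model_recovers_marginal_rate(self, rng):
        n = 2000
        X = rng.normal(size=(n, 3))
        arm = (rng.random(n) < 0.5).astype(int)
        y = (rng.random(n) < 0.3).astype(float)
        # 1-SE selection drops the noise covariates: predictions are flat
        # at the empirical rate for every X
        sparse = fit_outcome_models(
            X, arm, y, kind="binary_1y", seed=0, selection="1se"
        )
        # CV-min keeps small noise coefficients but stays centered
        dense = fit_outcome_models(X, arm, y, kind="binary_1y", seed=0)
        for a in (0, 1):
            rate = y[arm == a].mean()
            assert np.all(np.abs(sparse[a].predict(X) - rate) < 0.02)
            assert abs(dense[a].predict(X).mean() - rate) < 0.02

    def test_no_events_constant_zero(self, rng):
        X = rng.normal(size=(100, 2))
        arm = np.repeat([0, 1], 50)
        with pytest.warns(UserWarning):
            models = fit_outcome_models(X, arm, np.zeros(100), kind="binary_1y")
        assert np.all(models[0].predict(X) == 0)

    def test_small_arm_rejected(self, rng):
        X = rng.normal(size=(40, 2))
        arm = np.repeat([0, 1], [30, 10])
        with pytest.raises(ValueError):
            fit_outcome_models(X, arm, np.zeros(40), kind="binary_1y")

    def test_survival_constant_hazard_closed_form(self, rng):
        """Covariate-free pooled-logistic fit reproduces 1-(1-h)^T."""
        n, interval, horizon = 1500, 30, 720
        T = horizon // interval
        h = 0.08
        k = rng.geometric(h, size=2 * n)  # interval of event
        time = k * interval - rng.integers(0, interval, size=2 * n)
        event = np.ones(2 * n, dtype=int)
        # cap at horizon: survivors beyond T intervals are censored at horizon
        over = k > T
        time[over], event[over] = horizon, 0
        X = np.zeros((2 * n, 1))
        arm = np.repeat([0, 1], n)
        models = fit_outcome_models(
            X, arm, (time, event), kind="survival_horizon",
            horizon=horizon, interval_days=interval, seed=3,
        )
        for a in (0, 1):
            m = arm == a
            t_a, e_a = time[m], event[m]
            k_at_risk = np.maximum(np.ceil(np.minimum(t_a, horizon) / interval), 1)
            h_hat = ((e_a == 1) & (t_a <= horizon)).sum() / k_at_risk.sum()
            expected = 1 - (1 - h_hat) ** T
            assert models[a].predict(X[:1])[0] == pytest.approx(expected, abs=1e-6)

    def test_survival_no_events_zero(self, rng):
        X = rng.normal(size=(100, 2))
        arm = np.repeat([0, 1], 50)
        time = np.full(100, 400.0)
        with pytest.warns(UserWarning):
            models = fit_outcome_models(
                X, arm, (time, np.zeros(100, int)), kind="survival_horizon",
                horizon=730,
            )
        assert np.all(models[1].predict(X) == 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_outcome_models(np.zeros((60, 1)), np.repeat([0, 1], 30),
                               np.zeros(60), kind="cox")


class TestFastGLMs:
    def test_newton_logistic_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(500, 3))
        y = _bernoulli(rng, expit(0.3 + X[:, 0]))
        b0, b = newton_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        assert b0 == pytest.approx(ref[0], abs=1e-5)
        assert np.allclose(b, ref[1:], atol=1e-5)

    def test_newton_cloglog_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(800, 2))
        eta = -0.5 + 0.6 * X[:, 0]
        y = _bernoulli(rng, 1 - np.exp(-np.exp(eta)))
        b0, b = newton_cloglog(X, y)
        glm = sm.GLM(
            y, sm.add_constant(X),
            family=sm.families.Binomial(sm.families.links.CLogLog()),
        ).fit()
        assert b0 == pytest.approx(glm.params[0], abs=1e-4)
        assert np.allclose(b, glm.params[1:], atol=1e-4)
        pred = predict_cloglog(b0, b, X)
        assert np.all((pred > 0) & (pred < 1))
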
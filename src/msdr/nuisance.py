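"""Adaptive-LASSO-penalized propensity and outcome (nuisance) models.

The adaptive LASSO is fit in two stages: a ridge-penalized logistic fit
gives initial coefficients b_j, from which per-coefficient penalty weights
w_j = 1/(|b_j|^gamma + eps) are formed; the weighted L1 problem is then
solved over a penalty grid with the penalty chosen by K-fold
cross-validated deviance. Columns are standardized internally and
coefficients returned on the original scale. Ridge (rather than
unpenalized MLE) initial estimates keep stage 1 well-posed when the
feature count approaches the sample size after screening.

Outcome regressions come in three flavours: logistic models for the
binary 1-year and 2-year relapse indicators (fit per arm on patients with
the indicator observed), and a discrete-time pooled logistic hazard model
over 30-day intervals for the time-to-relapse outcome, from which the
event probability by the horizon is 1 - prod(1 - hazard).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

#: cap on adaptive weights: w_j = 1 / (|b_j|**gamma + ADAPTIVE_EPS)
ADAPTIVE_EPS = 1e-4

#: propensity scores are truncated into this interval (positivity guard)
PS_TRUNCATION = (0.01, 0.99)


@dataclass
class AdaptiveLassoFit:
    """Fitted adaptive-LASSO logistic model, coefficients on input scale."""

    intercept: float
    coef: np.ndarray
    lam: float
    adaptive_weights: np.ndarray
    gamma: float
    folds: int
    seed: int
    feature_names: Optional[list[str]] = None
    cv_deviance: Optional[dict] = field(default=None, repr=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return expit(self.intercept + X @ self.coef)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "coef": self.coef.tolist(),
                    "lam": self.lam,
                    "adaptive_weights": self.adaptive_weights.tolist(),
                    "gamma": self.gamma,
                    "folds": self.folds,
                    "seed": self.seed,
                    "feature_names": self.feature_names,
                },
                indent=2,
            )
        )


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Solve (1/n) sum logloss + lam * ||beta||_1 via liblinear."""
    n = len(y)
    C = 1.0 / max(lam * n, 1e-12)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-7,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    eta = np.clip(eta, -30, 30)
    return float(2 * np.sum(np.log1p(np.exp(eta)) - y * eta))


def fit_adaptive_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    gamma: float = 1.0,
    seed: int = 0,
    n_lambdas: int = 15,
    lambda_min_ratio: float = 1e-3,
    selection: str = "1se",
    feature_names: Optional[Sequence[str]] = None,
) -> AdaptiveLassoFit:
    """Two-stage adaptive LASSO logistic regression with CV penalty choice.

    ``selection='1se'`` (default) picks the sparsest penalty whose CV
    deviance is within one standard error of the minimum (the glmnet
    convention); ``'min'`` picks the deviance minimum. With ``gamma=0``
    the weights are exactly 1 and the fit reduces to a plain LASSO.
    Constant columns get coefficient 0. If every candidate penalty yields
    a degenerate fit (e.g. complete separation), the largest penalty is
    used with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else None

    if len(np.unique(y)) < 2:
        warnings.warn("degenerate outcome: all labels equal; returning constant model")
        mu = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
        return AdaptiveLassoFit(
            intercept=float(np.log(mu / (1 - mu))),
            coef=np.zeros(p),
            lam=np.inf,
            adaptive_weights=np.ones(p),
            gamma=gamma,
            folds=folds,
            seed=seed,
            feature_names=names,
        )

    mean, sd = X.mean(axis=0), X.std(axis=0)
    const = sd < 1e-12
    sd_safe = np.where(const, 1.0, sd)
    Xs = (X - mean) / sd_safe
    Xs[:, const] = 0.0

    # stage 1: ridge-penalized initial coefficients, ridge strength chosen
    # by the same K-fold CV (deviance); under a global null the selected
    # penalty is strong, the initial coefficients collapse into the eps
    # cap and the adaptive weights become near-uniform
    skf1 = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ridge_Cs = np.logspace(1.5, -3.5, 8)
    ridge_dev = np.zeros(len(ridge_Cs))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in skf1.split(Xs, y):
            for j, C in enumerate(ridge_Cs):
                r = LogisticRegression(
                    l1_ratio=0.0, C=C, solver="lbfgs", max_iter=500
                ).fit(Xs[tr], y[tr])
                eta = r.intercept_[0] + Xs[te] @ r.coef_[0]
                ridge_dev[j] += _deviance(eta, y[te])
        best_C = float(ridge_Cs[int(np.argmin(ridge_dev))])
        ridge = LogisticRegression(
            l1_ratio=0.0, C=best_C, solver="lbfgs", max_iter=2000
        ).fit(Xs, y)
    b_init = ridge.coef_[0]

    if gamma == 0:
        w = np.ones(p)
    else:
        w = 1.0 / (np.abs(b_init) ** gamma + ADAPTIVE_EPS)
    w = np.where(const, np.inf, w)
    Xw = np.where(np.isinf(w)[None, :], 0.0, Xs / np.where(np.isinf(w), 1.0, w))

    resid = y - y.mean()
    lam_max = float(np.max(np.abs(Xw.T @ resid)) / n) if p else 1.0
    lam_max = max(lam_max, 1e-8)
    grid = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambdas))
    ok = np.ones(n_lambdas, dtype=bool)
    for k, (tr, te) in enumerate(skf.split(Xw, y)):
        for j, lam in enumerate(grid):
            try:
                b0, beta = _l1_logistic(Xw[tr], y[tr], lam)
                dev[k, j] = _deviance(b0 + Xw[te] @ beta, y[te])
            except Exception:
                dev[k, j] = np.nan
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    ok &= np.isfinite(mean_dev)
    if not ok.any():
        warnings.warn("all CV fits degenerate; falling back to maximum penalty")
        best_j = 0
    else:
        masked = np.where(ok, mean_dev, np.inf)
        j_min = int(np.argmin(masked))
        if selection == "min":
            best_j = j_min
        else:
            # sparsest penalty within 1 SE of the minimum (grid descends)
            thresh = mean_dev[j_min] + se_dev[j_min]
            best_j = int(np.flatnonzero(ok & (mean_dev <= thresh))[0])
    lam = float(grid[best_j])

    b0, beta_w = _l1_logistic(Xw, y, lam)
    beta_std = np.where(np.isinf(w), 0.0, beta_w / np.where(np.isinf(w), 1.0, w))
    coef = beta_std / sd_safe
    coef[const] = 0.0
    intercept = b0 - float(mean @ coef)
    return AdaptiveLassoFit(
        intercept=intercept,
        coef=coef,
        lam=lam,
        adaptive_weights=np.where(np.isinf(w), 0.0, w),
        gamma=gamma,
        folds=folds,
        seed=seed,
        feature_names=names,
        cv_deviance={"grid": grid.tolist(), "mean_deviance": mean_dev.tolist()},
    )


def predict_propensity(fit: AdaptiveLassoFit, X: np.ndarray) -> np.ndarray:
    """Propensity scores truncated to [0.01, 0.99]."""
    return np.clip(fit.predict_proba(X), *PS_TRUNCATION)


@dataclass
class OutcomeModel:
    """Per-arm outcome regression m_a(X) of one of the three kinds."""

    kind: str
    fit: Optional[AdaptiveLassoFit]
    n_intervals: int = 0
    constant: Optional[float] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.constant is not None:
            return np.full(len(X), self.constant)
        if self.kind == "survival_horizon":
            h = np.clip(self.fit.predict_proba(X), 0.0, 1 - 1e-12)
            return 1.0 - (1.0 - h) ** self.n_intervals
        return self.fit.predict_proba(X)


def _expand_person_intervals(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: int,
    interval_days: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Person-interval expansion for the pooled logistic hazard model."""
    n_int = int(np.ceil(horizon / interval_days))
    t = np.minimum(time, horizon)
    # number of intervals each patient is at risk in (at least 1)
    k_at_risk = np.maximum(np.ceil(t / interval_days).astype(int), 1)
    rows = np.repeat(np.arange(len(t)), k_at_risk)
    Xe = X[rows]
    last = np.cumsum(k_at_risk) - 1
    ye = np.zeros(len(rows))
    ev_mask = (event == 1) & (time <= horizon)
    ye[last[ev_mask]] = 1.0
    return Xe, ye, n_int


def fit_outcome_models(
    X: np.ndarray,
    arm: np.ndarray,
    outcomes,
    kind: str = "binary_1y",
    horizon: int = 730,
    interval_days: int = 30,
    folds: int = 5,
    gamma: float = 1.0,
    seed: int = 0,
    n_lambdas: int = 15,
    selection: str = "min",
    min_arm_size: int = 25,
) -> dict[int, OutcomeModel]:
    """Fit per-arm outcome regressions m_a(X).

    For ``binary_1y``/``binary_2y``, ``outcomes`` is an array of 0/1
    indicators with NaN where the indicator is unobserved (censored before
    the horizon); each arm's model is fit on its observed subset. For
    ``survival_horizon``, ``outcomes`` is a ``(time, event)`` tuple of
    arrays and a pooled logistic discrete-hazard model (constant
    conditional hazard across 30-day intervals) is fit per arm.

    An arm with no events gets the constant model m_a = 0 with a warning.
    """
    if kind not in ("binary_1y", "binary_2y", "survival_horizon"):
        raise ValueError(f"unknown outcome kind {kind!r}")
    X = np.asarray(X, dtype=float)
    arm = np.asarray(arm).astype(int)
    models: dict[int, OutcomeModel] = {}
    for a in (0, 1):
        mask = arm == a
        if mask.sum() < min_arm_size:
            raise ValueError(f"arm {a} has fewer than {min_arm_size} patients")
        if kind == "survival_horizon":
            time, event = outcomes
            time = np.asarray(time, dtype=float)[mask]
            event = np.asarray(event).astype(int)[mask]
            if not ((event == 1) & (time <= horizon)).any():
                warnings.warn(f"arm {a}: no events by horizon; m_a set to 0")
                models[a] = OutcomeModel(kind=kind, fit=None, constant=0.0)
                continue
            Xe, ye, n_int = _expand_person_intervals(
                X[mask], time, event, horizon, interval_days
            )
            fit = fit_adaptive_lasso_logistic(
                Xe, ye, folds=folds, gamma=gamma, seed=seed + a,
                n_lambdas=n_lambdas, selection=selection,
            )
            models[a] = OutcomeModel(kind=kind, fit=fit, n_intervals=n_int)
        else:
            y = np.asarray(outcomes, dtype=float)[mask]
            obs = ~np.isnan(y)
            yo = y[obs]
            if len(yo) == 0 or yo.sum() == 0:
                warnings.warn(f"arm {a}: no observed events; m_a set to 0")
                models[a] = OutcomeModel(kind=kind, fit=None, constant=0.0)
                continue
            if yo.mean() == 1.0:
                models[a] = OutcomeModel(kind=kind, fit=None, constant=1.0)
                continue
            fit = fit_adaptive_lasso_logistic(
                X[mask][obs], yo, folds=folds, gamma=gamma, seed=seed + a,
                n_lambdas=n_lambdas, selection=selection,
            )
            models[a] = OutcomeModel(kind=kind, fit=fit)
    return models


def newton_cloglog(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-9, ridge: float = 1e-8
) -> tuple[float, np.ndarray]:
    """Binomial regression with complementary log-log link by Fisher scoring.

    P(Y=1|x) = 1 - exp(-exp(b0 + x'b)). This is the exactly-specified
    outcome model for a horizon indicator under an exponential
    proportional-hazards data-generating process with log-linear hazard.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pbar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    beta[0] = np.log(-np.log(1 - pbar))
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30.0, 3.0)
        mu = np.exp(eta)
        prob = np.clip(1.0 - np.exp(-mu), 1e-10, 1 - 1e-10)
        dp = mu * np.exp(-mu)  # d prob / d eta
        v = prob * (1 - prob)
        g = Xd.T @ ((y - prob) * dp / v)
        W = dp * dp / v
        H = (Xd * W[:, None]).T @ Xd + ridge * np.eye(p + 1)
        step = np.linalg.solve(H, g)
        beta = beta + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), beta[1:]


def predict_cloglog(intercept: float, coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.clip(intercept + np.asarray(X, dtype=float) @ coef, -30.0, 3.0)
    return 1.0 - np.exp(-np.exp(eta))


def newton_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-9, ridge: float = 1e-8
) -> tuple[float, np.ndarray]:
    """Unpenalized logistic regression by Newton-Raphson (fast path).

    Used by simulation-heavy diagnostics where thousands of small
    correctly-specified fits are needed; a tiny ridge keeps the Hessian
    invertible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    mu0 = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    beta[0] = np.log(mu0 / (1 - mu0))
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        g = Xd.T @ (y - mu)
        H = (Xd * w[:, None]).T @ Xd + ridge * np.eye(p + 1)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), beta[1:]
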
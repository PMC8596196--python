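"""Simulation studies over the synthetic cohorts.

These drive the analysis scripts and the acceptance checks: the
double-robustness experiment (each nuisance model misspecified in turn on
a confounded null cohort), estimand recovery against the truth oracle,
bootstrap CI coverage, empirical FDR of the marginal screen, and IPTW
balance. Problem sizes default to desk scale (minutes on one CPU);
every function is deterministic given its seed.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import assemble_cohort
from .estimation import aipw_binary, iptw_weights, smd_balance
from .features import FeatureMatrix, marginal_screen
from .inference import adjust_multiplicity, bootstrap_estimates, BootstrapSummary
from .nuisance import (
    fit_adaptive_lasso_logistic,
    newton_cloglog,
    newton_logistic,
    predict_cloglog,
    predict_propensity,
)
from .pipeline import _binary_obs_weights, estimate_all
from .simulate import SimConfig, simulate_cohort, true_estimands


def simulate_analysis_table(config: SimConfig) -> pd.DataFrame:
    """Simulate and assemble one analysis-ready cohort table.

    Returns one row per patient with arm, outcomes and the latent
    covariates z* joined on (oracle covariates for correctly-specified
    nuisance models).
    """
    patients, _, episodes, relapses = simulate_cohort(config)
    cohort = assemble_cohort(
        patients, episodes, relapses, config.drug_a, config.drug_b,
        tier="standard", horizons=config.horizons,
    )
    zcols = [c for c in patients.columns if c.startswith("z")]
    return cohort.merge(patients[["patient_id", *zcols]], on="patient_id")


def _fast_dr_rd(
    df: pd.DataFrame,
    horizon: int = 730,
    ps_correct: bool = True,
    or_correct: bool = True,
    zcols: tuple[str, ...] = ("z0",),
) -> dict:
    """AIPW 2-year risk difference with unpenalized logistic nuisances.

    Misspecification switches: ``ps_correct=False`` uses a constant
    (marginal) propensity; ``or_correct=False`` uses an intercept-only
    outcome regression.
    """
    Z = df[list(zcols)].to_numpy(dtype=float)
    arm = df["arm"].to_numpy(dtype=int)
    time = df["time_to_relapse_days"].to_numpy(dtype=float)
    event = df["event_indicator"].to_numpy(dtype=int)
    y, w = _binary_obs_weights(time, event, horizon)
    obs = ~np.isnan(y)

    if ps_correct:
        b0, b = newton_logistic(Z, arm)
        ps = np.clip(expit(b0 + Z @ b), 0.01, 0.99)
    else:
        ps = np.full(len(df), float(np.clip(arm.mean(), 0.01, 0.99)))

    m = {}
    for a in (0, 1):
        sel = obs & (arm == a)
        if or_correct:
            # cloglog link: exactly specified under the exponential hazard
            c0, cb = newton_cloglog(Z[sel], y[sel])
            m[a] = predict_cloglog(c0, cb, Z)
        else:
            m[a] = np.full(len(df), float(y[sel].mean()))
    est = aipw_binary(arm, y, w, ps, m[1], m[0], estimand=f"rd_{horizon}d")
    return {"estimate": est.contrast, "se": est.se, "dr": est}


def crude_rate_difference(df: pd.DataFrame, col: str = "relapse_2y") -> float:
    """Unadjusted complete-case rate difference between arms."""
    obs = df[col].notna()
    d = df[obs]
    return float(
        d.loc[d["arm"] == 1, col].astype(float).mean()
        - d.loc[d["arm"] == 0, col].astype(float).mean()
    )


def double_robustness_study(
    n: int = 4000, seed: int = 0, confounder=(0, 1.0, 0.7)
) -> dict:
    """Confounded null cohort: DR under each single misspecification.

    Returns the DR 2-year risk difference with (a) correct propensity +
    intercept-only outcome model and (b) correct outcome model + constant
    propensity, their influence-based SEs, and the crude (unadjusted)
    complete-case difference. The true risk difference is 0.
    """
    config = SimConfig(
        n_patients=n, confounder_spec=[tuple(confounder)],
        treatment_effect=0.0, seed=seed,
    )
    df = simulate_analysis_table(config)
    a = _fast_dr_rd(df, ps_correct=True, or_correct=False)
    b = _fast_dr_rd(df, ps_correct=False, or_correct=True)
    return {
        "dr_ps_correct": a["estimate"],
        "se_ps_correct": a["se"],
        "dr_or_correct": b["estimate"],
        "se_or_correct": b["se"],
        "crude": crude_rate_difference(df),
        "n": len(df),
    }


def estimand_recovery_study(
    n: int = 4000, seed: int = 0, log_hr: float = float(np.log(2)), n_mc: int = 100_000
) -> dict:
    """Nonnull cohort: adaptive-LASSO DR estimates vs the truth oracle."""
    config = SimConfig(
        n_patients=n, confounder_spec=[(0, 1.0, 0.7)],
        treatment_effect=log_hr, seed=seed,
    )
    df = simulate_analysis_table(config)
    zcols = [c for c in df.columns if c.startswith("z")]
    res = estimate_all(df, zcols, seed=seed)
    truth = true_estimands(config, n_mc=n_mc)
    truth_map = {
        "rd_1y": (truth.true_rd_1y, truth.mc_se["rd_1y"]),
        "rd_2y": (truth.true_rd_2y, truth.mc_se["rd_2y"]),
        "rr_nonrelapse": (truth.true_rr_nonrelapse_2y, truth.mc_se["rr_nonrelapse"]),
    }
    out = {"n": len(df)}
    for name, est in res["estimates"].items():
        tval, tse = truth_map[name]
        total_se = float(np.sqrt(est.se**2 + tse**2))
        out[name] = {
            "estimate": est.contrast,
            "truth": tval,
            "se": est.se,
            "mc_se": tse,
            "abs_z": abs(est.contrast - tval) / total_se,
        }
    return out


def coverage_study(
    n_cohorts: int = 200,
    n: int = 1500,
    B: int = 200,
    seed: int = 0,
    log_hr: float = float(np.log(1.5)),
) -> dict:
    """Bootstrap percentile-CI coverage of the 2-year risk difference.

    Each replicate simulates a fresh confounded cohort, bootstraps the
    AIPW estimate (correctly-specified logistic nuisances, IPCW for
    horizon censoring; the nuisance models are refit inside every
    resample) and records whether the 95% CI covers the oracle truth.
    """
    base = SimConfig(
        n_patients=n, n_icd=0, n_cpt=0, n_cui=0,
        confounder_spec=[(0, 1.0, 0.7)], treatment_effect=log_hr, seed=seed,
    )
    truth = true_estimands(base, n_mc=200_000).true_rd_2y

    def closure(d: pd.DataFrame) -> dict[str, float]:
        return {"rd_2y": _fast_dr_rd(d)["estimate"]}

    covered = 0
    widths = []
    for r in range(n_cohorts):
        cfg = SimConfig(
            n_patients=n, n_icd=0, n_cpt=0, n_cui=0,
            confounder_spec=[(0, 1.0, 0.7)], treatment_effect=log_hr,
            seed=seed + 17 * r + 1,
        )
        df = simulate_analysis_table(cfg)
        summaries = bootstrap_estimates(
            closure, df, B=B, seed=seed + 31 * r + 2, ratio_estimands=(),
        )
        lo, hi = summaries["rd_2y"].ci
        covered += int(lo <= truth <= hi)
        widths.append(hi - lo)
    return {
        "coverage": covered / n_cohorts,
        "truth": truth,
        "mean_ci_width": float(np.mean(widths)),
        "n_cohorts": n_cohorts,
        "n": n,
        "B": B,
    }


def fdr_study(
    n_reps: int = 500,
    n: int = 500,
    p: int = 200,
    q: float = 0.1,
    seed: int = 0,
    event_rate: float = 0.3,
) -> dict:
    """Empirical FDR of the marginal screen on pure-noise sparse features.

    Features are Bernoulli-gated negative-binomial counts independent of
    the binary label, so every retained full-EHR feature is a false
    discovery; the empirical FDR is the mean of V / max(R, 1).
    """
    rng = np.random.default_rng(seed)
    fdp = []
    n_retained = []
    cols = [f"noise_{j}" for j in range(p)]
    prov = pd.Series("full", index=cols)
    win = pd.Series("overall", index=cols)
    for _ in range(n_reps):
        occur = rng.random((n, p)) < 0.3
        X = occur * (1 + rng.negative_binomial(1.5, 0.5, size=(n, p)))
        y = (rng.random(n) < event_rate).astype(float)
        fm = FeatureMatrix(pd.DataFrame(X, columns=cols, dtype=float), prov, win)
        res = marginal_screen(fm, y, q=q)
        R = len(res.retained)
        fdp.append(R / max(R, 1) if R else 0.0)
        n_retained.append(R)
    return {
        "empirical_fdr": float(np.mean(fdp)),
        "mean_retained": float(np.mean(n_retained)),
        "n_reps": n_reps,
        "q": q,
    }


def balance_study(
    n: int = 5000,
    seed: int = 0,
    confounders=((0, 1.0, 0.7), (1, 0.6, 0.5)),
) -> dict:
    """Post-IPTW standardized mean differences of the designed confounders."""
    config = SimConfig(
        n_patients=n, confounder_spec=[tuple(c) for c in confounders],
        treatment_effect=0.0, seed=seed,
    )
    df = simulate_analysis_table(config)
    zcols = [c for c in df.columns if c.startswith("z")]
    X = df[zcols].to_numpy(dtype=float)
    arm = df["arm"].to_numpy(dtype=int)
    fit = fit_adaptive_lasso_logistic(
        X, arm, seed=seed, selection="min", feature_names=zcols
    )
    ps = predict_propensity(fit, X)
    w = iptw_weights(arm, ps)
    bal = smd_balance(df[zcols], arm, w)
    designed = [f"z{idx}" for idx, _, _ in confounders]
    return {
        "balance": bal,
        "designed": designed,
        "max_abs_smd_weighted": float(bal.loc[designed, "smd_weighted"].abs().max()),
        "max_abs_smd_unweighted": float(bal.loc[designed, "smd_unweighted"].abs().max()),
        "n": len(df),
    }


def independent_null_minp(
    B: int = 4000, k: int = 3, raw_target: float = 0.05, seed: int = 0
) -> dict:
    """Min-p adjustment on k independent null estimands with equal raw p.

    Builds bootstrap summaries whose draws are independent standard
    normals and whose point estimates sit at the two-sided
    ``raw_target`` tail, then runs the min-p adjustment. Under
    independence the adjusted p is approximately 1 - (1 - raw)^k.
    """
    rng = np.random.default_rng(seed)
    summaries = {}
    for j in range(k):
        draws = rng.standard_normal(B)
        point = float(np.quantile(draws, 1 - raw_target / 2))
        # center draws at the point so the null value 0 sits in the tail
        summaries[f"e{j}"] = BootstrapSummary(
            estimand=f"e{j}", point=point, draws=draws + point,
            p_raw=float(
                2 * min(np.mean(draws + point <= 0), np.mean(draws + point >= 0))
            ),
            null_value=0.0, seed=seed,
        )
    adj = adjust_multiplicity(summaries)
    return {
        "raw": {name: s.p_raw for name, s in summaries.items()},
        "adjusted": adj,
        "expected_independent": 1 - (1 - raw_target) ** k,
    }
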
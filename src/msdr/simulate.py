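"""Synthetic two-arm EHR cohort generator with known causal ground truth.

Emulates the statistical structure of a registry-linked EHR comparative
effectiveness study of MS disease-modifying therapies (DMTs):

* confounding by indication — treatment assignment follows a logistic model
  on latent patient covariates that also drive relapse hazard;
* sparse high-dimensional coded features (ICD diagnoses, CPT procedures,
  CUI narrative concepts) whose occurrence loads on the same latent
  covariates, so feature screening has true positives;
* relapse times from an exponential proportional-hazards model (constant
  baseline hazard, which gives closed-form counterfactual survival for the
  truth oracle);
* administrative plus random censoring, independent of covariates by
  default (switchable to covariate-dependent for IPCW stress tests).

All dates are integer day offsets from a fixed epoch (day 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

DAYS_PER_YEAR = 365.0

#: fraction of CUI mentions that are positive (non-negated); negated
#: mentions are dropped at feature ingestion.
CUI_POSITIVE_FRACTION = 0.85


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Parameters
    ----------
    n_patients:
        Cohort size before eligibility filtering.
    n_icd, n_cpt, n_cui:
        Vocabulary sizes for diagnosis, procedure and narrative-concept
        codes.
    sparsity:
        Target mean fraction of patients with any occurrence per code,
        in (0, 1). Per-code occurrence probabilities are drawn around this
        target so the <10% sparsity filter has work to do.
    confounder_spec:
        List of ``(latent index, effect on treatment log-odds, effect on
        relapse log-hazard)`` triples. A nonzero product of the two effects
        creates confounding by indication.
    treatment_effect:
        Log hazard ratio of arm 1 (drug_b) vs arm 0 (drug_a).
    baseline_hazard:
        Relapse events per year at covariate zero in arm 0.
    censor_rate:
        Administrative censoring hazard per year (exponential), combined
        with a hard administrative cutoff ``admin_censor_days`` after the
        index date.
    horizons:
        Event-free evaluation times in days, strictly increasing.
    seed:
        Seed for all randomness in :func:`simulate_cohort`.
    """

    n_patients: int = 2000
    n_icd: int = 60
    n_cpt: int = 40
    n_cui: int = 40
    sparsity: float = 0.2
    n_latent: int = 3
    confounder_spec: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(0, 1.0, 0.7)]
    )
    treatment_effect: float = 0.0
    baseline_hazard: float = 0.25
    censor_rate: float = 0.2
    admin_censor_days: int = 1825
    censor_on_covariates: bool = False
    horizons: tuple[int, ...] = (365, 730)
    drug_a: str = "dimethyl fumarate"
    drug_b: str = "fingolimod"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if min(self.n_icd, self.n_cpt, self.n_cui) < 0:
            raise ConfigurationError("vocabulary sizes must be >= 0")
        if not (0.0 < self.sparsity < 1.0):
            raise ConfigurationError("sparsity must be in (0, 1)")
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline_hazard must be >= 0")
        hz = tuple(self.horizons)
        if any(b <= a for a, b in zip(hz, hz[1:])):
            raise ConfigurationError("horizons must be strictly increasing")
        for idx, _, _ in self.confounder_spec:
            if not (0 <= idx < self.n_latent):
                raise ConfigurationError(
                    f"confounder index {idx} outside latent dimension"
                )


@dataclass
class EstimandTruth:
    """Counterfactual ground truth for the three relapse estimands.

    ``true_rd_1y`` / ``true_rd_2y`` are risk differences (arm 1 minus
    arm 0) of relapse by 365 / 730 days on the probability scale;
    ``true_rr_nonrelapse_2y`` is the ratio of arm-wise event-free
    probabilities at 730 days. ``mc_se`` holds the Monte-Carlo standard
    error of each, keyed by estimand name.
    """

    true_rd_1y: float
    true_rd_2y: float
    true_rr_nonrelapse_2y: float
    mc_se: dict[str, float]
    n_mc: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EstimandTruth":
        return cls(**json.loads(Path(path).read_text()))


def _treatment_logits(config: SimConfig, Z: np.ndarray) -> np.ndarray:
    eta = np.zeros(len(Z))
    for idx, on_trt, _ in config.confounder_spec:
        eta += on_trt * Z[:, idx]
    return eta


def _hazard_loglinear(config: SimConfig, Z: np.ndarray, arm: np.ndarray) -> np.ndarray:
    """Relapse hazard per year under the proportional-hazards model."""
    eta = np.full(len(Z), np.log(max(config.baseline_hazard, 1e-300)))
    for idx, _, on_haz in config.confounder_spec:
        eta += on_haz * Z[:, idx]
    eta += config.treatment_effect * np.asarray(arm, dtype=float)
    return np.exp(eta) if config.baseline_hazard > 0 else np.zeros(len(Z))


def _code_events(
    rng: np.random.Generator,
    config: SimConfig,
    Z: np.ndarray,
    index_day: np.ndarray,
    vocab: str,
    n_codes: int,
) -> pd.DataFrame:
    """Sparse covariate-linked code occurrences for one vocabulary.

    Occurrence of code j is Bernoulli with a logit offset loading on one
    latent covariate (half the codes are informative); counts given
    occurrence are 1 + negative binomial. Event days are uniform over the
    two years before the index date.
    """
    n = len(Z)
    if n_codes == 0:
        return pd.DataFrame(
            columns=["patient_id", "day", "vocab", "code", "count", "positive"]
        )
    # per-code marginal occurrence probability around the sparsity target
    a = 2.0
    b = a * (1.0 - config.sparsity) / config.sparsity
    p_code = np.clip(rng.beta(a, b, size=n_codes), 0.01, 0.90)
    # the MS diagnostic code is frequent by construction
    if vocab == "ICD":
        p_code[0] = 0.85
    dim = rng.integers(0, config.n_latent, size=n_codes)
    loading = np.where(
        rng.random(n_codes) < 0.5, rng.normal(0.0, 0.5, size=n_codes), 0.0
    )
    if vocab == "ICD":
        loading[0] = 0.4
        dim[0] = config.confounder_spec[0][0] if config.confounder_spec else 0
    eta = logit(p_code)[None, :] + loading[None, :] * Z[:, dim]
    occur = rng.random((n, n_codes)) < expit(eta)
    pat, cod = np.nonzero(occur)
    counts = 1 + rng.negative_binomial(1.5, 0.5, size=len(pat))
    lookback = rng.integers(1, 721, size=len(pat))
    days = np.maximum(index_day[pat] - lookback, 0)
    out = pd.DataFrame(
        {
            "patient_id": pat,
            "day": days,
            "vocab": vocab,
            "code": np.char.add(f"{vocab}_", np.char.zfill(cod.astype(str), 3)),
            "count": counts,
            "positive": 1,
        }
    )
    if vocab == "CUI":
        out["positive"] = (rng.random(len(out)) < CUI_POSITIVE_FRACTION).astype(int)
    return out


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (patients, events, episodes, relapses).

    patients: patient_id, sex, race, birth_offset, index_day, arm,
    censor_day (absolute day of end of follow-up) and the latent covariate
    columns ``z0..z{k-1}`` (available to tests as oracle covariates; a real
    study would not observe them).

    events: one row per (patient, code) occurrence with an aggregate count
    and a representative day before the index date.

    episodes: DMT episodes including the index episode (drug_a for arm 0,
    drug_b for arm 1) and, for a random subset, a prior standard-efficacy
    episode.

    relapses: prior relapses (before the index date) and the first
    post-index relapse when it occurs before censoring; days are absolute.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    Z = rng.standard_normal((n, config.n_latent))
    arm = (rng.random(n) < expit(_treatment_logits(config, Z))).astype(int)

    index_day = rng.integers(400, 1500, size=n)
    age = np.clip(rng.normal(40.0, 10.0, size=n), 18.0, 70.0)
    sex = np.where(rng.random(n) < 0.75, "F", "M")
    race = np.where(rng.random(n) < 0.85, "non-hispanic white", "other")
    birth_offset = (index_day - np.round(age * 365.25)).astype(int)

    # relapse time (days after index) under exponential PH
    lam = _hazard_loglinear(config, Z, arm)  # per year
    with np.errstate(divide="ignore"):
        t_years = np.where(
            lam > 0, rng.exponential(1.0, size=n) / np.maximum(lam, 1e-300), np.inf
        )
    t_day = np.ceil(t_years * DAYS_PER_YEAR)

    # censoring: exponential hazard + administrative cutoff
    c_rate = np.full(n, config.censor_rate)
    if config.censor_on_covariates:
        c_rate = c_rate * np.exp(0.4 * Z[:, 0])
    with np.errstate(divide="ignore"):
        c_years = np.where(
            c_rate > 0, rng.exponential(1.0, size=n) / np.maximum(c_rate, 1e-300), np.inf
        )
    c_day = np.minimum(
        np.ceil(c_years * DAYS_PER_YEAR), config.admin_censor_days
    ).astype(int)
    c_day = np.maximum(c_day, 1)

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "sex": sex,
            "race": race,
            "birth_offset": birth_offset,
            "index_day": index_day,
            "arm": arm,
            "censor_day": index_day + c_day,
        }
    )
    for k in range(config.n_latent):
        patients[f"z{k}"] = Z[:, k]

    events = pd.concat(
        [
            _code_events(rng, config, Z, index_day, "ICD", config.n_icd),
            _code_events(rng, config, Z, index_day, "CPT", config.n_cpt),
            _code_events(rng, config, Z, index_day, "CUI", config.n_cui),
        ],
        ignore_index=True,
    )

    # DMT episodes: index episode + prior standard-efficacy DMT for ~40%
    drugs = np.where(arm == 0, config.drug_a, config.drug_b)
    idx_episodes = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "drug": drugs,
            "start_day": index_day,
            "end_day": index_day + c_day,
        }
    )
    prior_mask = rng.random(n) < 0.4
    prior_ids = np.nonzero(prior_mask)[0]
    prior_drug = rng.choice(
        ["interferon-beta", "glatiramer acetate"], size=len(prior_ids)
    )
    prior_start = index_day[prior_ids] - rng.integers(100, 800, size=len(prior_ids))
    prior_end = index_day[prior_ids] - rng.integers(1, 50, size=len(prior_ids))
    prior_episodes = pd.DataFrame(
        {
            "patient_id": prior_ids,
            "drug": prior_drug,
            "start_day": np.maximum(prior_start, 0),
            "end_day": np.maximum(prior_end, 1),
        }
    )
    episodes = (
        pd.concat([prior_episodes, idx_episodes], ignore_index=True)
        .sort_values(["patient_id", "start_day"])
        .reset_index(drop=True)
    )

    # prior relapses: Poisson count loading on the confounder covariates
    eta_prior = np.full(n, 0.2)
    for idx, _, on_haz in config.confounder_spec:
        eta_prior += 0.4 * on_haz * Z[:, idx]
    n_prior = rng.poisson(np.exp(np.clip(eta_prior, -5, 3)))
    rows = np.repeat(np.arange(n), n_prior)
    prior_days = index_day[rows] - rng.integers(1, 731, size=len(rows))
    prior_rel = pd.DataFrame(
        {
            "patient_id": rows,
            "day": np.maximum(prior_days, 0),
            "type": rng.choice(["clinical", "radiologic"], size=len(rows), p=[0.7, 0.3]),
        }
    )
    observed = t_day <= c_day
    post_rel = pd.DataFrame(
        {
            "patient_id": np.nonzero(observed)[0],
            "day": (index_day[observed] + t_day[observed]).astype(int),
            "type": rng.choice(
                ["clinical", "radiologic"], size=int(observed.sum()), p=[0.7, 0.3]
            ),
        }
    )
    relapses = (
        pd.concat([prior_rel, post_rel], ignore_index=True)
        .sort_values(["patient_id", "day"])
        .reset_index(drop=True)
    )
    return patients, events, episodes, relapses


def true_estimands(config: SimConfig, n_mc: int = 100_000) -> EstimandTruth:
    """Monte-Carlo oracle for the counterfactual estimands.

    Draws ``n_mc`` latent covariate vectors and evaluates both potential
    outcomes per draw through the closed-form exponential survival function
    (no censoring), i.e. the Rao-Blackwellised conditional event
    probabilities ``F_a(h | Z) = 1 - exp(-lambda_a(Z) h)``. Risk
    differences are ``mean(F_1 - F_0)``; the non-relapse relative risk is
    ``mean(S_1) / mean(S_0)`` at the last horizon, with a delta-method
    Monte-Carlo SE accounting for the covariance of the arm-wise survival
    draws.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10,000")
    rng = np.random.default_rng(config.seed + 1_000_003)
    Z = rng.standard_normal((n_mc, config.n_latent))
    lam0 = _hazard_loglinear(config, Z, np.zeros(n_mc))
    lam1 = _hazard_loglinear(config, Z, np.ones(n_mc))

    h1, h2 = config.horizons[0] / DAYS_PER_YEAR, config.horizons[-1] / DAYS_PER_YEAR
    F0_1, F1_1 = 1 - np.exp(-lam0 * h1), 1 - np.exp(-lam1 * h1)
    F0_2, F1_2 = 1 - np.exp(-lam0 * h2), 1 - np.exp(-lam1 * h2)
    S0_2, S1_2 = 1 - F0_2, 1 - F1_2

    rd1 = F1_1 - F0_1
    rd2 = F1_2 - F0_2
    m0, m1 = S0_2.mean(), S1_2.mean()
    if m0 <= 0:
        rr, se_rr = np.inf, np.inf
    else:
        rr = m1 / m0
        cov = np.cov(S1_2, S0_2)
        var_rr = (
            cov[0, 0] / m0**2
            - 2 * m1 * cov[0, 1] / m0**3
            + m1**2 * cov[1, 1] / m0**4
        ) / n_mc
        se_rr = float(np.sqrt(max(var_rr, 0.0)))
    return EstimandTruth(
        true_rd_1y=float(rd1.mean()),
        true_rd_2y=float(rd2.mean()),
        true_rr_nonrelapse_2y=float(rr),
        mc_se={
            # floored: the conditional-probability oracle is exact under
            # the null, but mc_se must stay positive
            "rd_1y": max(float(rd1.std(ddof=1) / np.sqrt(n_mc)), 1e-12),
            "rd_2y": max(float(rd2.std(ddof=1) / np.sqrt(n_mc)), 1e-12),
            "rr_nonrelapse": max(float(se_rr), 1e-12),
        },
        n_mc=n_mc,
    )
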
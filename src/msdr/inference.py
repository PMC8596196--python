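"""Bootstrap inference, min-p multiplicity adjustment and E-values.

Patient-level resampling with replacement re-runs the full nuisance-plus-
DR pipeline per replicate; 95% CIs are percentile intervals and the raw
two-sided p-value is 2 * min(fraction of draws <= null, fraction >= null)
with null 0 for differences and 1 for ratios (ratios are handled on the
log scale internally). Multiplicity across the three relapse estimands is
adjusted with a min-p step-down resampling procedure computed from the
same bootstrap draws. Unmeasured-confounding sensitivity uses the
closed-form E-value E = RR* + sqrt(RR*(RR*-1)) on the risk-ratio scale,
with E* from the CI limit closer to the null; risk differences are
converted to an approximate risk ratio from the DR per-arm means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class BootstrapError(RuntimeError):
    """Too many failed bootstrap replicates."""


@dataclass
class BootstrapSummary:
    """Bootstrap draws and inference for one estimand."""

    estimand: str
    point: float
    draws: np.ndarray = field(repr=False)
    ci: tuple[float, float] = (np.nan, np.nan)
    p_raw: float = np.nan
    p_adjusted: Optional[float] = None
    null_value: float = 0.0
    is_ratio: bool = False
    seed: int = 0
    n_failures: int = 0

    @property
    def B(self) -> int:
        return len(self.draws)


@dataclass
class EValueResult:
    """Minimal unmeasured-confounding strength for point and CI bound."""

    E: float
    E_star: float
    formula: str = "closed-form RR"

    def __post_init__(self) -> None:
        if self.E < 1 or self.E_star < 1:
            raise ValueError("E-values are bounded below by 1")


def _raw_pvalue(draws: np.ndarray, null: float) -> float:
    lo = float(np.mean(draws <= null))
    hi = float(np.mean(draws >= null))
    return min(1.0, 2.0 * min(lo, hi))


def bootstrap_estimates(
    pipeline: Callable[[pd.DataFrame], dict[str, float]],
    data: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    nulls: Optional[dict[str, float]] = None,
    ratio_estimands: Sequence[str] = ("rr_nonrelapse",),
    max_failure_fraction: float = 0.05,
) -> dict[str, BootstrapSummary]:
    """Patient-level bootstrap of a whole estimation pipeline.

    ``pipeline`` maps a cohort table to a dict of point estimates and is
    re-run on every resample, so nuisance-model refitting is included in
    the interval. Failed replicates (e.g. an empty arm) are redrawn and
    counted; more than ``max_failure_fraction`` failures aborts.
    Deterministic given ``seed``.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    point = pipeline(data)
    names = list(point)
    nulls = dict(nulls or {})
    for name in names:
        nulls.setdefault(name, 1.0 if name in ratio_estimands else 0.0)

    n = len(data)
    draws = np.empty((B, len(names)))
    failures = 0
    max_failures = int(np.ceil(max_failure_fraction * B))
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            res = pipeline(data.iloc[idx].reset_index(drop=True))
            draws[b] = [res[name] for name in names]
            b += 1
        except Exception as exc:  # noqa: BLE001 — replicate-level failure
            failures += 1
            logger.debug("bootstrap replicate failed: %s", exc)
            if failures > max_failures:
                raise BootstrapError(
                    f"{failures} failed replicates (> {max_failure_fraction:.0%} of B)"
                ) from exc

    summaries: dict[str, BootstrapSummary] = {}
    for j, name in enumerate(names):
        d = draws[:, j]
        # (B+1)*alpha order-statistic convention for percentile intervals
        ci = (
            float(np.quantile(d, 0.025, method="weibull")),
            float(np.quantile(d, 0.975, method="weibull")),
        )
        if not (ci[0] <= point[name] <= ci[1]):
            logger.warning(
                "bootstrap CI for %s does not bracket the point estimate", name
            )
        summaries[name] = BootstrapSummary(
            estimand=name,
            point=float(point[name]),
            draws=d,
            ci=ci,
            p_raw=_raw_pvalue(d, nulls[name]),
            null_value=nulls[name],
            is_ratio=name in ratio_estimands,
            seed=seed,
            n_failures=failures,
        )
    adjust_multiplicity(summaries)
    return summaries


def adjust_multiplicity(summaries: dict[str, BootstrapSummary]) -> dict[str, float]:
    """Min-p step-down adjustment across estimands sharing resamples.

    Each estimand's draws are centered at its point estimate (on the log
    scale for ratios) to approximate the null resampling distribution;
    per-replicate pseudo p-values come from each estimand's own empirical
    two-sided tail, and the adjusted p for estimand j is the fraction of
    replicates whose minimum pseudo p across estimands is <= j's raw p.
    Monotonicity (step-down and adjusted >= raw) is enforced. Results are
    written back onto the summaries and returned.
    """
    names = list(summaries)
    Bs = {summaries[k].B for k in names}
    if len(Bs) != 1:
        raise ValueError("estimands must share the same number of replicates")
    (B,) = Bs
    if len(names) == 1:
        s = summaries[names[0]]
        s.p_adjusted = s.p_raw
        return {s.estimand: s.p_raw}

    centered = np.empty((B, len(names)))
    for j, name in enumerate(names):
        s = summaries[name]
        if s.is_ratio:
            if s.point <= 0 or np.any(s.draws <= 0):
                raise ValueError("ratio draws must be positive for log centering")
            centered[:, j] = np.log(s.draws) - np.log(s.point)
        else:
            centered[:, j] = s.draws - s.point

    # empirical two-sided pseudo p-value of each centered draw within its
    # own column (midrank to keep values in (0, 1))
    pseudo = np.empty_like(centered)
    for j in range(len(names)):
        c = centered[:, j]
        order = np.argsort(c, kind="stable")
        ranks = np.empty(B)
        ranks[order] = np.arange(1, B + 1)
        F = (ranks - 0.5) / B
        pseudo[:, j] = 2.0 * np.minimum(F, 1.0 - F)
    min_p = pseudo.min(axis=1)

    raw = np.array([summaries[name].p_raw for name in names])
    adj = np.array([float(np.mean(min_p <= r)) for r in raw])
    adj = np.maximum(adj, raw)
    # step-down monotonicity: adjusted p nondecreasing in raw-p order
    order = np.argsort(raw, kind="stable")
    running = 0.0
    for idx in order:
        running = max(running, adj[idx])
        adj[idx] = min(running, 1.0)
    out = {}
    for j, name in enumerate(names):
        summaries[name].p_adjusted = float(adj[j])
        out[name] = float(adj[j])
    return out


def _evalue_point(rr: float) -> float:
    rr_star = max(rr, 1.0 / rr)
    return rr_star + np.sqrt(rr_star * (rr_star - 1.0))


def evalue_rr(
    rr_point: float, rr_ci: Optional[tuple[float, float]] = None
) -> EValueResult:
    """Closed-form E-value for a risk ratio.

    E = RR* + sqrt(RR*(RR*-1)) with RR* = max(RR, 1/RR); E* applies the
    same formula to the CI limit closer to 1, and is 1 when the CI
    crosses 1.
    """
    if rr_point <= 0:
        raise ValueError("risk ratio must be positive")
    E = float(_evalue_point(rr_point))
    if rr_ci is None:
        E_star = E
    else:
        lo, hi = rr_ci
        if lo <= 0:
            raise ValueError("CI limits must be positive")
        if lo <= 1.0 <= hi:
            E_star = 1.0
        else:
            limit = lo if lo > 1.0 else hi
            E_star = float(_evalue_point(limit))
    if E_star > E + 1e-12:
        warnings.warn("E* exceeds E; CI limit farther from null than the point")
    return EValueResult(E=E, E_star=min(E_star, E))


def evalue_rd(
    p1: float, p0: float, ci_means: Optional[tuple[float, float]] = None
) -> EValueResult:
    """Approximate E-value for a risk difference via the DR per-arm means.

    Converts the risk difference to the risk ratio p1/p0 of the adjusted
    per-arm event probabilities and applies the closed-form risk-ratio
    E-value; ``ci_means`` optionally gives a CI for that ratio. Documented
    as an approximation.
    """
    if not (0 < p1 < 1) or not (0 < p0 < 1):
        raise ValueError("per-arm probabilities must lie in (0, 1)")
    rr = p1 / p0
    res = evalue_rr(rr, ci_means)
    return EValueResult(E=res.E, E_star=res.E_star, formula="RD->RR approximation")
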
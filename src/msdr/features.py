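"""Expert-defined and high-dimensional full-EHR confounder construction.

Feature matrices are built over pre-treatment windows measured backward
from each patient's index date — 3 months (90 days), 6 months (180 days)
or the overall history — with half-open intervals ``(index - w, index]``.

Expert-defined features follow standard MS comparative-effectiveness
practice: health-care utilization on a log(1 + count) scale, MS diagnosis
and narrative-concept frequencies normalized by utilization, normalized
procedure frequencies for corticosteroids, MRI, hospitalization and
emergency visits, prior-DMT exposure, prior relapse counts and
demographics. Full-EHR features are windowed counts of every rolled-up
PheCode, CPT group and positively-mentioned CUI; sparsity filtering and
marginal screening with Benjamini-Hochberg FDR control reduce them to the
confounder set used by the nuisance models. Expert features are exempt
from both filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

WINDOW_DAYS = {"3mo": 90, "6mo": 180, "overall": None}


class MappingError(ValueError):
    """Inconsistent code-rollup mapping."""


@dataclass
class FeatureMatrix:
    """Patients x features matrix with provenance and window metadata.

    ``provenance`` maps each column to 'expert' or 'full'; ``window`` maps
    each column to its lookback tag. No missing values: absent codes are 0.
    """

    data: pd.DataFrame
    provenance: pd.Series
    window: pd.Series

    def __post_init__(self) -> None:
        cols = self.data.columns
        self.provenance = self.provenance.reindex(cols)
        self.window = self.window.reindex(cols)
        if self.provenance.isna().any() or self.data.isna().any().any():
            raise ValueError("feature matrix has missing values or metadata")
        bad = set(self.window.dropna()) - set(WINDOW_DAYS)
        if bad:
            raise ValueError(f"unknown window tags {bad}")

    @property
    def expert_columns(self) -> list[str]:
        return list(self.data.columns[self.provenance == "expert"])

    @property
    def full_columns(self) -> list[str]:
        return list(self.data.columns[self.provenance == "full"])

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        cols = [c for c in self.data.columns if c in set(columns)]
        return FeatureMatrix(
            self.data[cols], self.provenance[cols], self.window[cols]
        )

    @classmethod
    def concat(cls, parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        return cls(
            pd.concat([p.data for p in parts], axis=1),
            pd.concat([p.provenance for p in parts]),
            pd.concat([p.window for p in parts]),
        )


@dataclass
class ScreenResult:
    """Outcome of marginal screening with BH FDR control at level q."""

    pvalues: pd.Series
    q: float
    retained: list[str]
    rejected_mask: pd.Series


@dataclass
class ExpertCodeSets:
    """Code groups entering the expert-defined EHR features."""

    ms_icd: frozenset = frozenset({"ICD_000"})
    ms_cui: frozenset = frozenset({"CUI_000", "CUI_001"})
    steroid_cpt: frozenset = frozenset({"CPT_000", "CPT_001"})
    mri_cpt: frozenset = frozenset({"CPT_002", "CPT_003", "CPT_004"})
    hospitalization_cpt: frozenset = frozenset({"CPT_005"})
    emergency_cpt: frozenset = frozenset({"CPT_006"})


def drop_negated_cuis(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only positive CUI mentions; ICD/CPT rows pass through."""
    if "positive" not in events.columns:
        return events
    keep = (events["vocab"] != "CUI") | (events["positive"].fillna(1) == 1)
    return events[keep]


def rollup_icd_to_phecode(
    events: pd.DataFrame, mapping: pd.DataFrame
) -> pd.DataFrame:
    """Roll ICD diagnosis counts up to PheCodes (many-to-one).

    ``mapping`` has columns (icd, phecode). PheCode counts are the sum of
    member ICD counts; unmapped ICD codes are dropped with a logged tally.
    An ICD code mapped to two PheCodes is a mapping error.
    """
    dup = mapping.groupby("icd")["phecode"].nunique()
    if (dup > 1).any():
        raise MappingError(
            f"ICD codes mapped to multiple PheCodes: {list(dup[dup > 1].index)}"
        )
    icd = events[events["vocab"] == "ICD"]
    merged = icd.merge(mapping.drop_duplicates(), left_on="code", right_on="icd")
    n_dropped = len(icd) - len(merged)
    if n_dropped:
        logger.info("rollup_icd_to_phecode: dropped %d unmapped ICD rows", n_dropped)
    if merged.empty:
        return pd.DataFrame(columns=["patient_id", "phecode", "count"])
    return (
        merged.groupby(["patient_id", "phecode"], as_index=False)["count"]
        .sum()
        .sort_values(["patient_id", "phecode"])
        .reset_index(drop=True)
    )


def rollup_cpt(
    events: pd.DataFrame,
    grouping: pd.DataFrame,
    mri_exceptions: Sequence[str] = (),
) -> pd.DataFrame:
    """Consolidate CPT procedure codes into groups.

    ``grouping`` has columns (cpt, group). Codes in ``mri_exceptions``
    (MS-relevant MRI of orbit, brain, spine) are kept as individual
    features even if the grouping also covers them.
    """
    exceptions = set(mri_exceptions)
    overlap = exceptions & set(grouping["cpt"])
    if overlap:
        warnings.warn(
            f"CPT codes in both grouping and exceptions kept individual: {sorted(overlap)}"
        )
    cpt = events[events["vocab"] == "CPT"].copy()
    if cpt.empty:
        return pd.DataFrame(columns=["patient_id", "group", "count"])
    gmap = grouping.drop_duplicates("cpt").set_index("cpt")["group"]
    grp = cpt["code"].map(gmap)
    grp = np.where(cpt["code"].isin(exceptions), cpt["code"], grp)
    cpt["group"] = grp
    n_dropped = int(cpt["group"].isna().sum())
    if n_dropped:
        logger.info("rollup_cpt: dropped %d ungrouped CPT rows", n_dropped)
    cpt = cpt.dropna(subset=["group"])
    return (
        cpt.groupby(["patient_id", "group"], as_index=False)["count"]
        .sum()
        .sort_values(["patient_id", "group"])
        .reset_index(drop=True)
    )


def _window_mask(events: pd.DataFrame, index_day: pd.Series, window: str) -> pd.Series:
    idx = events["patient_id"].map(index_day)
    w = WINDOW_DAYS[window]
    mask = events["day"] <= idx
    if w is not None:
        mask &= events["day"] > idx - w
    return mask


def _cat_count(ev: pd.DataFrame, codes: frozenset, pids: pd.Index) -> pd.Series:
    sub = ev[ev["code"].isin(codes)]
    return (
        sub.groupby("patient_id")["count"].sum().reindex(pids, fill_value=0)
    ).astype(float)


def expert_features(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    relapses: pd.DataFrame,
    episodes: pd.DataFrame,
    code_sets: ExpertCodeSets | None = None,
) -> FeatureMatrix:
    """Build the expert-defined feature matrix, one row per patient.

    Utilization is log(1 + all-ICD count + note/CUI count); normalized
    frequencies divide category counts by the raw (unlogged) utilization
    or, for MS ICD frequency, by the all-ICD count. Zero denominators give
    a 0 feature with a warning. Relapse inputs are the registry-style
    relapse table (days absolute); only relapses strictly before the index
    date count as history.
    """
    cs = code_sets or ExpertCodeSets()
    pats = patients.set_index("patient_id")
    pids = pats.index
    index_day = pats["index_day"]
    events = drop_negated_cuis(events)
    events = events[events["patient_id"].isin(pids)]

    cols: dict[str, pd.Series] = {}
    window_tag: dict[str, str] = {}
    zero_denoms = 0

    def norm(num: pd.Series, den: pd.Series) -> pd.Series:
        nonlocal zero_denoms
        zero_denoms += int(((den == 0) & (num == 0)).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        return out.where(den > 0, 0.0)

    for wname in ("3mo", "6mo", "overall"):
        ev = events[_window_mask(events, index_day, wname)]
        icd = ev[ev["vocab"] == "ICD"]
        cui = ev[ev["vocab"] == "CUI"]
        icd_count = (
            icd.groupby("patient_id")["count"].sum().reindex(pids, fill_value=0)
        ).astype(float)
        cui_count = (
            cui.groupby("patient_id")["count"].sum().reindex(pids, fill_value=0)
        ).astype(float)
        raw_util = icd_count + cui_count
        if wname in ("3mo", "overall"):
            cols[f"utilization|{wname}"] = np.log1p(raw_util)
            window_tag[f"utilization|{wname}"] = wname
            cols[f"norm_ms_icd|{wname}"] = norm(
                _cat_count(icd, cs.ms_icd, pids), icd_count
            )
            cols[f"norm_ms_cui|{wname}"] = norm(
                _cat_count(cui, cs.ms_cui, pids), raw_util
            )
            cols[f"norm_steroid_cpt|{wname}"] = norm(
                _cat_count(ev, cs.steroid_cpt, pids), raw_util
            )
            for name in ("norm_ms_icd", "norm_ms_cui", "norm_steroid_cpt"):
                window_tag[f"{name}|{wname}"] = wname
        if wname in ("6mo", "overall"):
            cols[f"norm_mri_cpt|{wname}"] = norm(
                _cat_count(ev, cs.mri_cpt, pids), raw_util
            )
            window_tag[f"norm_mri_cpt|{wname}"] = wname
        if wname == "overall":
            cols["norm_hospitalization|overall"] = norm(
                _cat_count(ev, cs.hospitalization_cpt, pids), raw_util
            )
            cols["norm_emergency|overall"] = norm(
                _cat_count(ev, cs.emergency_cpt, pids), raw_util
            )
            window_tag["norm_hospitalization|overall"] = "overall"
            window_tag["norm_emergency|overall"] = "overall"

    if zero_denoms:
        warnings.warn(
            f"expert_features: {zero_denoms} zero-denominator normalized values set to 0"
        )

    # prior DMT exposure: episode days before index, in months
    ep = episodes[episodes["patient_id"].isin(pids)].copy()
    ep_idx = ep["patient_id"].map(index_day)
    end = ep["end_day"].fillna(ep_idx).clip(upper=ep_idx)
    dur = (end - ep["start_day"]).clip(lower=0)
    dur = dur.where(ep["start_day"] < ep_idx, 0)
    months = (
        dur.groupby(ep["patient_id"]).sum().reindex(pids, fill_value=0) / 30.44
    )
    cols["months_prior_dmt"] = months
    window_tag["months_prior_dmt"] = "overall"

    rel = relapses[relapses["patient_id"].isin(pids)]
    rel_idx = rel["patient_id"].map(index_day)
    for years, name in ((1, "relapses_prior_1y"), (2, "relapses_prior_2y")):
        in_win = (rel["day"] < rel_idx) & (rel["day"] >= rel_idx - 365 * years)
        cols[name] = (
            rel[in_win].groupby("patient_id").size().reindex(pids, fill_value=0)
        ).astype(float)
        window_tag[name] = "overall"

    cols["age_years"] = (index_day - pats["birth_offset"]) / 365.25
    cols["sex_female"] = (pats["sex"] == "F").astype(float)
    cols["race_nonhispanic_white"] = (
        pats["race"].str.contains("white", case=False).astype(float)
        if "race" in pats
        else pd.Series(0.0, index=pids)
    )
    icd_all = events[events["vocab"] == "ICD"]
    ms_first = (
        icd_all[icd_all["code"].isin(cs.ms_icd)]
        .groupby("patient_id")["day"]
        .min()
        .reindex(pids)
    )
    any_first = events.groupby("patient_id")["day"].min().reindex(pids)
    cols["disease_duration_years"] = ((index_day - ms_first) / 365.25).fillna(0.0).clip(
        lower=0
    )
    cols["followup_duration_years"] = ((index_day - any_first) / 365.25).fillna(
        0.0
    ).clip(lower=0)
    for name in (
        "age_years",
        "sex_female",
        "race_nonhispanic_white",
        "disease_duration_years",
        "followup_duration_years",
    ):
        window_tag[name] = "overall"

    data = pd.DataFrame(cols, index=pids).astype(float)
    prov = pd.Series("expert", index=data.columns)
    win = pd.Series({c: window_tag[c] for c in data.columns})
    return FeatureMatrix(data, prov, win)


def full_ehr_features(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    phecode_map: pd.DataFrame,
    cpt_groups: pd.DataFrame,
    mri_exceptions: Sequence[str] = (),
    windows: Sequence[str] = ("3mo", "overall"),
) -> FeatureMatrix:
    """Windowed counts of every PheCode, CPT group and positive CUI."""
    pats = patients.set_index("patient_id")
    pids = pats.index
    events = drop_negated_cuis(events)
    events = events[events["patient_id"].isin(pids)]
    parts: dict[str, pd.Series] = {}
    win_tag: dict[str, str] = {}
    for wname in windows:
        ev = events[_window_mask(events, pats["index_day"], wname)]
        phe = rollup_icd_to_phecode(ev, phecode_map)
        for code, grp in phe.groupby("phecode"):
            name = f"phe:{code}|{wname}"
            parts[name] = grp.set_index("patient_id")["count"]
            win_tag[name] = wname
        cpt = rollup_cpt(ev, cpt_groups, mri_exceptions)
        for code, grp in cpt.groupby("group"):
            name = f"cpt:{code}|{wname}"
            parts[name] = grp.set_index("patient_id")["count"]
            win_tag[name] = wname
        cui = ev[ev["vocab"] == "CUI"]
        for code, grp in cui.groupby("code"):
            name = f"cui:{code}|{wname}"
            parts[name] = grp.groupby("patient_id")["count"].sum()
            win_tag[name] = wname
    if parts:
        data = pd.DataFrame(parts, index=pids).fillna(0.0).astype(float)
    else:
        data = pd.DataFrame(index=pids)
    prov = pd.Series("full", index=data.columns)
    return FeatureMatrix(data, prov, pd.Series(win_tag).reindex(data.columns))


def sparsity_filter(matrix: FeatureMatrix, threshold: float = 0.10) -> FeatureMatrix:
    """Drop full-EHR features present in < ``threshold`` of patients.

    A feature counts as present in a patient when its value is nonzero.
    Features with nonzero frequency exactly at the threshold are kept
    ('less than 10%' removal rule); expert features are never removed.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    freq = (matrix.data != 0).mean(axis=0)
    keep = (matrix.provenance == "expert") | (freq >= threshold)
    return matrix.select(list(matrix.data.columns[keep]))


def _univariate_logistic_pvalues(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """Wald p-values from per-column logistic regressions (intercept+slope).

    Vectorized 2-parameter Newton-Raphson across columns; degenerate
    (constant) columns and non-converged fits get p = 1.
    """
    n, p = X.shape
    y = y.astype(float)
    sd = X.std(axis=0)
    const = sd < 1e-12
    Xs = np.where(const[None, :], 0.0, (X - X.mean(axis=0)) / np.where(const, 1.0, sd))
    a = np.full(p, np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0)
    b = np.zeros(p)
    h00 = h01 = h11 = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = np.clip(a[None, :] + Xs * b[None, :], -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y[:, None] - mu
        g0, g1 = r.sum(axis=0), (Xs * r).sum(axis=0)
        h00, h01, h11 = w.sum(axis=0), (w * Xs).sum(axis=0), (w * Xs * Xs).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (-h01 * g0 + h00 * g1) / det
        da, db = np.clip(da, -5, 5), np.clip(db, -5, 5)
        a, b = a + np.nan_to_num(da), b + np.nan_to_num(db)
        if np.nanmax(np.abs(np.concatenate([da, db]))) < tol:
            break
    det = h00 * h11 - h01**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b = np.sqrt(h00 / det)
        z = b / se_b
    pvals = 2 * norm.sf(np.abs(z))
    pvals = np.where(const | ~np.isfinite(pvals) | (np.abs(b) > 4.9), 1.0, pvals)
    return pvals


def marginal_screen(
    matrix: FeatureMatrix, labels: np.ndarray | pd.Series, q: float = 0.1
) -> ScreenResult:
    """Screen full-EHR features by marginal logistic association.

    One univariate logistic regression per full-EHR feature against the
    binary relapse label; Benjamini-Hochberg step-up at FDR level ``q``
    retains the significant features. Expert features bypass screening and
    are always retained.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    y = np.asarray(labels, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 patients for screening")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary")
    full_cols = matrix.full_columns
    pvals = pd.Series(1.0, index=matrix.data.columns)
    rejected = pd.Series(False, index=matrix.data.columns)
    if full_cols:
        pv = _univariate_logistic_pvalues(matrix.data[full_cols].to_numpy(), y)
        pvals[full_cols] = pv
        rej, _, _, _ = multipletests(pv, alpha=q, method="fdr_bh")
        rejected[full_cols] = rej
    retained = matrix.expert_columns + [c for c in full_cols if rejected[c]]
    return ScreenResult(pvalues=pvals, q=q, retained=retained, rejected_mask=rejected)


def toy_phecode_map(n_icd: int, prefix: str = "ICD") -> pd.DataFrame:
    """Synthetic many-to-one ICD -> PheCode map (pairs of ICD codes)."""
    icds = [f"{prefix}_{i:03d}" for i in range(n_icd)]
    return pd.DataFrame(
        {"icd": icds, "phecode": [f"PHE_{i // 2:03d}" for i in range(n_icd)]}
    )


def toy_cpt_groups(n_cpt: int, n_mri_exceptions: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic CPT -> group table plus MS-relevant MRI exception codes."""
    cpts = [f"CPT_{i:03d}" for i in range(n_cpt)]
    groups = pd.DataFrame(
        {"cpt": cpts, "group": [f"CPTGRP_{i // 4:03d}" for i in range(n_cpt)]}
    )
    mri = [f"CPT_{i:03d}" for i in range(2, 2 + n_mri_exceptions)]
    return groups, mri
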
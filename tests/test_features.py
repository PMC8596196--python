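"""Feature engineering: rollups, expert features vs a brute-force oracle,
sparsity filtering and BH-screened marginal association."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from msdr.features import (
    ExpertCodeSets,
    FeatureMatrix,
    MappingError,
    expert_features,
    full_ehr_features,
    marginal_screen,
    rollup_cpt,
    rollup_icd_to_phecode,
    sparsity_filter,
    toy_cpt_groups,
    toy_phecode_map,
    _univariate_logistic_pvalues,
)
from msdr.simulate import SimConfig, simulate_cohort


def _events(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "day", "vocab", "code", "count"]
    ).assign(positive=1)


class TestRollups:
    def test_phecode_additivity(self):
        ev = _events([(1, 5, "ICD", "A", 3), (1, 9, "ICD", "B", 2)])
        mapping = pd.DataFrame({"icd": ["A", "B"], "phecode": ["P1", "P1"]})
        out = rollup_icd_to_phecode(ev, mapping)
        assert out.loc[0, "count"] == 5

    def test_empty_events(self):
        out = rollup_icd_to_phecode(_events([]), toy_phecode_map(4))
        assert out.empty

    def test_duplicate_mapping_raises(self):
        mapping = pd.DataFrame({"icd": ["A", "A"], "phecode": ["P1", "P2"]})
        with pytest.raises(MappingError):
            rollup_icd_to_phecode(_events([(1, 1, "ICD", "A", 1)]), mapping)

    def test_random_rollup_matches_groupby_oracle(self, rng):
        codes = [f"ICD_{i:03d}" for i in range(50)]
        rows = [
            (int(rng.integers(0, 20)), int(rng.integers(0, 100)), "ICD",
             codes[rng.integers(0, 50)], int(rng.integers(1, 5)))
            for _ in range(400)
        ]
        ev = _events(rows)
        mapping = toy_phecode_map(50)
        out = rollup_icd_to_phecode(ev, mapping).set_index(["patient_id", "phecode"])
        # independent oracle: explicit dict accumulation
        expected = {}
        code_to_phe = dict(zip(mapping.icd, mapping.phecode))
        for pid, _, _, code, cnt in rows:
            key = (pid, code_to_phe[code])
            expected[key] = expected.get(key, 0) + cnt
        assert len(out) == len(expected)
        for key, val in expected.items():
            assert out.loc[key, "count"] == val

    def test_cpt_exception_kept_individual(self):
        ev = _events([(1, 1, "CPT", "CPT_002", 2), (1, 2, "CPT", "CPT_003", 1)])
        groups, mri = toy_cpt_groups(8)
        with pytest.warns(UserWarning):
            out = rollup_cpt(ev, groups, mri)
        assert set(out["group"]) == {"CPT_002", "CPT_003"}

    def test_cpt_grouping_additivity(self):
        ev = _events([(1, 1, "CPT", "CPT_000", 2), (1, 2, "CPT", "CPT_001", 3)])
        groups, _ = toy_cpt_groups(8)
        out = rollup_cpt(ev, groups, mri_exceptions=[])
        assert out.loc[0, "count"] == 5 and out.loc[0, "group"] == "CPTGRP_000"


def _oracle_expert_row(pid, patients, events, relapses, episodes, cs):
    """Independent per-patient scan over raw rows."""
    pat = patients[patients.patient_id == pid].iloc[0]
    idx = pat.index_day
    ev = [
        r for r in events.itertuples()
        if r.patient_id == pid and not (r.vocab == "CUI" and r.positive == 0)
    ]

    def in_window(day, w):
        return day <= idx and (w is None or day > idx - w)

    out = {}
    for wname, w in (("3mo", 90), ("6mo", 180), ("overall", None)):
        icd = sum(r.count for r in ev if r.vocab == "ICD" and in_window(r.day, w))
        cui = sum(r.count for r in ev if r.vocab == "CUI" and in_window(r.day, w))
        util = icd + cui
        ms_icd = sum(
            r.count for r in ev
            if r.vocab == "ICD" and r.code in cs.ms_icd and in_window(r.day, w)
        )
        ms_cui = sum(
            r.count for r in ev
            if r.vocab == "CUI" and r.code in cs.ms_cui and in_window(r.day, w)
        )

        def cat(codes):
            return sum(r.count for r in ev if r.code in codes and in_window(r.day, w))

        if wname in ("3mo", "overall"):
            out[f"utilization|{wname}"] = np.log1p(util)
            out[f"norm_ms_icd|{wname}"] = ms_icd / icd if icd else 0.0
            out[f"norm_ms_cui|{wname}"] = ms_cui / util if util else 0.0
            out[f"norm_steroid_cpt|{wname}"] = (
                cat(cs.steroid_cpt) / util if util else 0.0
            )
        if wname in ("6mo", "overall"):
            out[f"norm_mri_cpt|{wname}"] = cat(cs.mri_cpt) / util if util else 0.0
        if wname == "overall":
            out["norm_hospitalization|overall"] = (
                cat(cs.hospitalization_cpt) / util if util else 0.0
            )
            out["norm_emergency|overall"] = (
                cat(cs.emergency_cpt) / util if util else 0.0
            )
    months = 0.0
    for r in episodes.itertuples():
        if r.patient_id == pid and r.start_day < idx:
            end = idx if pd.isna(r.end_day) else min(r.end_day, idx)
            months += max(end - r.start_day, 0) / 30.44
    out["months_prior_dmt"] = months
    for years, name in ((1, "relapses_prior_1y"), (2, "relapses_prior_2y")):
        out[name] = float(
            sum(
                1 for r in relapses.itertuples()
                if r.patient_id == pid and idx - 365 * years <= r.day < idx
            )
        )
    return out


def test_expert_features_match_bruteforce_oracle(small_cohort_tables):
    config, (patients, events, episodes, relapses) = small_cohort_tables
    pats = patients.head(30)
    cs = ExpertCodeSets()
    fm = expert_features(pats, events, relapses, episodes, cs)
    for pid in pats.patient_id.head(12):
        expected = _oracle_expert_row(pid, pats, events, relapses, episodes, cs)
        for name, val in expected.items():
            assert fm.data.loc[pid, name] == pytest.approx(val, abs=1e-9), name


def test_expert_feature_normalized_example():
    """10 MS ICD codes among 20 total ICD codes -> normalized frequency 0.5."""
    rows = [(1, 10, "ICD", "ICD_000", 10), (1, 20, "ICD", "ICD_001", 10)]
    patients = pd.DataFrame(
        {"patient_id": [1], "sex": ["F"], "race": ["non-hispanic white"],
         "birth_offset": [-10000], "index_day": [100], "censor_day": [800]}
    )
    fm = expert_features(
        patients, _events(rows), pd.DataFrame(columns=["patient_id", "day"]),
        pd.DataFrame(columns=["patient_id", "drug", "start_day", "end_day"]),
    )
    assert fm.data.loc[1, "norm_ms_icd|overall"] == 0.5
    assert fm.data.loc[1, "utilization|overall"] == pytest.approx(np.log(21))


def test_no_events_gives_zero_features():
    patients = pd.DataFrame(
        {"patient_id": [1], "sex": ["M"], "race": ["other"],
         "birth_offset": [-9000], "index_day": [500], "censor_day": [900]}
    )
    with pytest.warns(UserWarning, match="zero-denominator"):
        fm = expert_features(
            patients, _events([]), pd.DataFrame(columns=["patient_id", "day"]),
            pd.DataFrame(columns=["patient_id", "drug", "start_day", "end_day"]),
        )
    windowed = [c for c in fm.data.columns if "|" in c]
    assert (fm.data.loc[1, windowed] == 0).all()


def test_negated_cuis_dropped():
    rows = pd.DataFrame(
        {
            "patient_id": [1, 1],
            "day": [10, 20],
            "vocab": ["CUI", "CUI"],
            "code": ["CUI_000", "CUI_000"],
            "count": [4, 9],
            "positive": [1, 0],
        }
    )
    patients = pd.DataFrame(
        {"patient_id": [1], "sex": ["F"], "race": ["other"],
         "birth_offset": [-9000], "index_day": [100], "censor_day": [900]}
    )
    fm = expert_features(
        patients, rows, pd.DataFrame(columns=["patient_id", "day"]),
        pd.DataFrame(columns=["patient_id", "drug", "start_day", "end_day"]),
    )
    # only the positive mention (count 4) contributes
    assert fm.data.loc[1, "utilization|overall"] == pytest.approx(np.log1p(4))


def test_feature_construction_invariant_to_row_order(small_cohort_tables):
    config, (patients, events, episodes, relapses) = small_cohort_tables
    pats = patients.head(40)
    fm1 = expert_features(pats, events, relapses, episodes)
    shuffled = events.sample(frac=1.0, random_state=3).reset_index(drop=True)
    fm2 = expert_features(pats, shuffled, relapses, episodes)
    pd.testing.assert_frame_equal(fm1.data, fm2.data)


def _noise_matrix(n, p, rng, prefix="f"):
    cols = [f"{prefix}{j}" for j in range(p)]
    data = pd.DataFrame(rng.poisson(1.0, size=(n, p)), columns=cols, dtype=float)
    return FeatureMatrix(
        data, pd.Series("full", index=cols), pd.Series("overall", index=cols)
    )


class TestSparsityFilter:
    def _matrix_with_frequency(self, k, n=100):
        cols = ["expertish", "target"]
        data = pd.DataFrame(0.0, index=range(n), columns=cols)
        data.iloc[:k, 1] = 1.0
        data.iloc[:, 0] = 1.0
        prov = pd.Series(["expert", "full"], index=cols)
        win = pd.Series(["overall", "overall"], index=cols)
        return FeatureMatrix(data, prov, win)

    def test_below_threshold_removed(self):
        fm = sparsity_filter(self._matrix_with_frequency(9))
        assert "target" not in fm.data.columns

    def test_exactly_at_threshold_retained(self):
        fm = sparsity_filter(self._matrix_with_frequency(10))
        assert "target" in fm.data.columns

    def test_all_zero_removed_and_expert_kept(self):
        fm = self._matrix_with_frequency(0)
        out = sparsity_filter(fm)
        assert list(out.data.columns) == ["expertish"]


class TestMarginalScreen:
    def test_pvalues_match_statsmodels(self, rng):
        n, p = 300, 5
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 0.4).astype(float)
        ours = _univariate_logistic_pvalues(X, y)
        for j in range(p):
            fit = sm.Logit(y, sm.add_constant(X[:, j])).fit(disp=0)
            assert ours[j] == pytest.approx(fit.pvalues[1], rel=1e-4, abs=1e-6)

    def test_constant_feature_p_one(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = (rng.random(100) < 0.5).astype(float)
        p = _univariate_logistic_pvalues(X, y)
        assert p[0] == 1.0

    def test_signal_feature_retained_noise_mostly_not(self, rng):
        n = 800
        signal = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * signal))).astype(float)
        fm = _noise_matrix(n, 20, rng)
        fm.data["signal"] = signal
        fm = FeatureMatrix(
            fm.data,
            pd.Series("full", index=fm.data.columns),
            pd.Series("overall", index=fm.data.columns),
        )
        res = marginal_screen(fm, y, q=0.1)
        assert "signal" in res.retained
        assert len(res.retained) < 6

    def test_expert_features_bypass_screen(self, rng):
        fm = _noise_matrix(50, 3, rng)
        prov = fm.provenance.copy()
        prov.iloc[0] = "expert"
        fm = FeatureMatrix(fm.data, prov, fm.window)
        y = (rng.random(50) < 0.5).astype(float)
        res = marginal_screen(fm, y, q=0.1)
        assert fm.data.columns[0] in res.retained

    def test_retained_shrinks_with_q(self, rng):
        n = 600
        X = rng.normal(size=(n, 30))
        y = (rng.random(n) < 1 / (1 + np.exp(-(X[:, :5] * 0.5).sum(1)))).astype(float)
        cols = [f"x{j}" for j in range(30)]
        fm = FeatureMatrix(
            pd.DataFrame(X, columns=cols),
            pd.Series("full", index=cols),
            pd.Series("overall", index=cols),
        )
        sizes = [
            len(marginal_screen(fm, y, q=q).retained) for q in (0.2, 0.1, 0.02)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_retained_is_prefix_of_pvalue_order(self, rng):
        n = 500
        X = rng.normal(size=(n, 25))
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        cols = [f"x{j}" for j in range(25)]
        fm = FeatureMatrix(
            pd.DataFrame(X, columns=cols),
            pd.Series("full", index=cols),
            pd.Series("overall", index=cols),
        )
        res = marginal_screen(fm, y, q=0.1)
        k = len(res.retained)
        smallest = set(res.pvalues.nsmallest(k).index)
        assert set(res.retained) == smallest

    def test_too_few_patients_rejected(self, rng):
        fm = _noise_matrix(10, 2, rng)
        with pytest.raises(ValueError):
            marginal_screen(fm, np.zeros(10), q=0.1)


def test_full_ehr_features_nonnegative_and_dense(small_cohort_tables):
    config, (patients, events, episodes, relapses) = small_cohort_tables
    pats = patients.head(50)
    groups, mri = toy_cpt_groups(config.n_cpt)
    fm = full_ehr_features(pats, events, toy_phecode_map(config.n_icd), groups, mri)
    assert not fm.data.isna().any().any()
    assert (fm.data.to_numpy() >= 0).all()
    assert set(fm.provenance) == {"full"}
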
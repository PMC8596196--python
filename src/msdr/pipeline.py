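"""End-to-end pipeline: assemble -> featurize -> screen -> fit -> estimate
-> bootstrap -> sensitivity, with stage artifacts and a run manifest.

Each stage is runnable on its own over the previous stage's CSV/JSON
artifacts (see :mod:`msdr.cli`); :func:`run_pipeline` chains them. All
randomness is driven by explicit seeds recorded in the manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import assemble_cohort
from .estimation import (
    aipw_binary,
    censoring_survival,
    dr_survival_ratio,
    iptw_weights,
    km_curve,
    smd_balance,
    CENSOR_WEIGHT_FLOOR,
)
from .features import (
    ExpertCodeSets,
    FeatureMatrix,
    expert_features,
    full_ehr_features,
    marginal_screen,
    sparsity_filter,
    toy_cpt_groups,
    toy_phecode_map,
)
from .inference import adjust_multiplicity, bootstrap_estimates, evalue_rd, evalue_rr
from .nuisance import (
    fit_adaptive_lasso_logistic,
    fit_outcome_models,
    predict_propensity,
)
from .simulate import SimConfig, simulate_cohort, true_estimands


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    data_dir: str = "data"
    out_dir: str = "results/run"
    drug_a: str = "dimethyl fumarate"
    drug_b: str = "fingolimod"
    tier: str = "standard"
    horizons: tuple[int, int] = (365, 730)
    q: float = 0.1
    sparsity_threshold: float = 0.10
    folds: int = 5
    n_lambdas: int = 15
    gamma: float = 1.0
    interval_days: int = 30
    B: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        obj = cls(**cfg)
        if obj.tier not in ("standard", "higher"):
            raise PipelineError("config", "bad_tier", f"tier {obj.tier!r}")
        return obj

    def table_path(self, name: str) -> Path:
        return Path(self.data_dir) / f"{name}.csv"


TABLE_SCHEMAS = {
    "patients": ["patient_id", "sex", "birth_offset", "index_day", "censor_day"],
    "events": ["patient_id", "day", "vocab", "code", "count"],
    "episodes": ["patient_id", "drug", "start_day", "end_day"],
    "relapses": ["patient_id", "day", "type"],
}


def write_simulated_cohort(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate and write patients/events/episodes/relapses CSVs + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, events, episodes, relapses = simulate_cohort(config)
    patients.to_csv(out / "patients.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    episodes.to_csv(out / "episodes.csv", index=False)
    relapses.to_csv(out / "relapses.csv", index=False)
    truth = true_estimands(config, n_mc=100_000)
    truth.to_json(out / "truth.json")
    return {
        "n_patients": len(patients),
        "n_events": len(events),
        "n_relapses": len(relapses),
    }


def validate_tables(data_dir: str | Path) -> dict:
    """Schema and referential-integrity report over the input tables."""
    data_dir = Path(data_dir)
    report: dict = {"tables": {}, "violations": 0}
    frames = {}
    for name, cols in TABLE_SCHEMAS.items():
        path = data_dir / f"{name}.csv"
        entry = {"path": str(path), "rows": 0, "missing_columns": [], "problems": []}
        if not path.exists():
            entry["problems"].append("file not found")
            report["violations"] += 1
        else:
            df = pd.read_csv(path)
            frames[name] = df
            entry["rows"] = len(df)
            entry["missing_columns"] = [c for c in cols if c not in df.columns]
            report["violations"] += len(entry["missing_columns"])
        report["tables"][name] = entry
    if "patients" in frames:
        pats = frames["patients"]
        dup = int(pats["patient_id"].duplicated().sum())
        if dup:
            report["tables"]["patients"]["problems"].append(
                f"{dup} duplicated patient ids"
            )
            report["violations"] += dup
        known = set(pats["patient_id"])
        for name in ("events", "episodes", "relapses"):
            if name in frames and "patient_id" in frames[name]:
                orphans = int((~frames[name]["patient_id"].isin(known)).sum())
                if orphans:
                    report["tables"][name]["problems"].append(
                        f"{orphans} rows reference unknown patients"
                    )
                    report["violations"] += orphans
    return report


def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    frames = {}
    for name in TABLE_SCHEMAS:
        path = config.table_path(name)
        if not path.exists():
            raise PipelineError("ingest", "file_not_found", str(path))
        frames[name] = pd.read_csv(path)
    return frames


def build_features(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    relapses: pd.DataFrame,
    episodes: pd.DataFrame,
    code_sets: Optional[ExpertCodeSets] = None,
    phecode_map: Optional[pd.DataFrame] = None,
    cpt_groups: Optional[pd.DataFrame] = None,
    mri_exceptions: Sequence[str] = (),
) -> FeatureMatrix:
    """Expert + full-EHR feature matrix for the given patients.

    Defaults to the synthetic toy mappings when none are supplied.
    """
    if phecode_map is None:
        n_icd = events.loc[events["vocab"] == "ICD", "code"].nunique() or 1
        phecode_map = toy_phecode_map(max(n_icd, 2))
    if cpt_groups is None:
        n_cpt = events.loc[events["vocab"] == "CPT", "code"].nunique() or 1
        cpt_groups, mri_exceptions = toy_cpt_groups(max(n_cpt, 4))
    exp = expert_features(patients, events, relapses, episodes, code_sets)
    full = full_ehr_features(
        patients, events, phecode_map, cpt_groups, mri_exceptions
    )
    return FeatureMatrix.concat([exp, full])


def save_feature_matrix(fm: FeatureMatrix, out_dir: str | Path, stem: str = "features"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fm.data.rename_axis("patient_id").to_csv(out / f"{stem}.csv")
    meta = pd.DataFrame(
        {"feature": fm.data.columns, "provenance": fm.provenance.values,
         "window": fm.window.fillna("overall").values}
    )
    meta.to_csv(out / f"{stem}_meta.csv", index=False)


def load_feature_matrix(out_dir: str | Path, stem: str = "features") -> FeatureMatrix:
    out = Path(out_dir)
    data = pd.read_csv(out / f"{stem}.csv", index_col="patient_id")
    meta = pd.read_csv(out / f"{stem}_meta.csv").set_index("feature")
    return FeatureMatrix(
        data, meta["provenance"], meta["window"].reindex(data.columns)
    )


def _binary_obs_weights(time, event, horizon) -> tuple[np.ndarray, np.ndarray]:
    """IPCW observation weights and indicator for a horizon-binary outcome."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    y = ((event == 1) & (time <= horizon)).astype(float)
    observed = (y == 1) | (time >= horizon)
    G = censoring_survival(time, event, np.minimum(time, horizon))
    G = np.maximum(G, CENSOR_WEIGHT_FLOOR)
    w = observed.astype(float) / G
    return np.where(observed, y, np.nan), w


def estimate_all(
    cohort: pd.DataFrame,
    feature_cols: Sequence[str],
    horizons: tuple[int, int] = (365, 730),
    folds: int = 5,
    gamma: float = 1.0,
    n_lambdas: int = 15,
    interval_days: int = 30,
    seed: int = 0,
    selection: str = "min",
) -> dict:
    """Fit nuisances and compute the three DR estimates on one cohort table.

    Nuisance penalties default to the CV-deviance minimum (``selection``):
    for doubly robust estimation the nuisance fits should predict well,
    and the extra shrinkage of the 1-SE rule leaves residual confounding.

    ``cohort`` must hold arm, time_to_relapse_days, event_indicator and
    the feature columns. Returns the DREstimate objects plus the fitted
    propensity model and scores (for balance diagnostics).
    """
    X = cohort[list(feature_cols)].to_numpy(dtype=float)
    arm = cohort["arm"].to_numpy(dtype=int)
    time = cohort["time_to_relapse_days"].to_numpy(dtype=float)
    event = cohort["event_indicator"].to_numpy(dtype=int)
    h1, h2 = horizons

    ps_fit = fit_adaptive_lasso_logistic(
        X, arm, folds=folds, gamma=gamma, seed=seed, n_lambdas=n_lambdas,
        selection=selection, feature_names=list(feature_cols),
    )
    ps = predict_propensity(ps_fit, X)

    estimates = {}
    for h, name, kind in ((h1, "rd_1y", "binary_1y"), (h2, "rd_2y", "binary_2y")):
        y, w = _binary_obs_weights(time, event, h)
        models = fit_outcome_models(
            X, arm, np.where(np.isnan(y), np.nan, y), kind=kind,
            folds=folds, gamma=gamma, seed=seed + h, n_lambdas=n_lambdas,
            selection=selection,
        )
        estimates[name] = aipw_binary(
            arm, y, w, ps, models[1].predict(X), models[0].predict(X), estimand=name
        )
    surv_models = fit_outcome_models(
        X, arm, (time, event), kind="survival_horizon", horizon=h2,
        interval_days=interval_days, folds=folds, gamma=gamma, seed=seed + 7,
        n_lambdas=n_lambdas, selection=selection,
    )
    estimates["rr_nonrelapse"] = dr_survival_ratio(
        arm, time, event, ps,
        surv_models[1].predict(X), surv_models[0].predict(X), horizon=h2,
    )
    return {
        "estimates": estimates,
        "ps_fit": ps_fit,
        "ps": ps,
        "surv_models": surv_models,
    }


def dr_incidence_curves(
    cohort: pd.DataFrame,
    surv_models: dict,
    feature_cols: Sequence[str],
    horizon: int,
    interval_days: int = 30,
) -> pd.DataFrame:
    """DR-adjusted mean cumulative incidence per arm over time.

    Standardizes the pooled-logistic hazard predictions over the whole
    cohort's covariate distribution (g-computation curve).
    """
    rows = []
    n_int = int(np.ceil(horizon / interval_days))
    for a, model in surv_models.items():
        if model.fit is None:
            haz = np.full(len(cohort), model.constant or 0.0)
        else:
            X = cohort[list(feature_cols)].to_numpy(dtype=float)
            haz = np.clip(model.fit.predict_proba(X), 0, 1 - 1e-12)
        for k in range(n_int + 1):
            rows.append(
                {
                    "time": k * interval_days,
                    "arm": a,
                    "incidence": float(np.mean(1 - (1 - haz) ** k)),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage end-to-end; returns the Table-2-style report.

    Writes per-stage artifacts under ``config.out_dir`` and a manifest with
    versions, seeds and row counts. Any stage failure raises
    :class:`PipelineError` carrying the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "msdr_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    frames = _load_tables(config)

    try:
        cohort = assemble_cohort(
            frames["patients"], frames["episodes"], frames["relapses"],
            config.drug_a, config.drug_b, tier=config.tier,
            horizons=config.horizons,
        )
    except Exception as exc:
        raise PipelineError("assemble", "assembly_failed", str(exc)) from exc
    if cohort.empty:
        raise PipelineError("assemble", "empty_cohort", "no patients assigned")
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest["stages"]["assemble"] = {"rows": len(cohort)}

    try:
        kept = frames["patients"][
            frames["patients"]["patient_id"].isin(cohort["patient_id"])
        ]
        fm = build_features(
            kept, frames["events"], frames["relapses"], frames["episodes"]
        )
    except Exception as exc:
        raise PipelineError("featurize", "feature_failed", str(exc)) from exc
    save_feature_matrix(fm, out)
    manifest["stages"]["featurize"] = {"features": fm.data.shape[1]}

    try:
        fm = sparsity_filter(fm, config.sparsity_threshold)
        labels = (
            cohort.set_index("patient_id")["relapse_2y"]
            .reindex(fm.data.index)
            .fillna(0)
            .astype(int)
        )
        screen = marginal_screen(fm, labels.to_numpy(), q=config.q)
        fm = fm.select(screen.retained)
    except Exception as exc:
        raise PipelineError("screen", "screen_failed", str(exc)) from exc
    save_feature_matrix(fm, out, stem="features_screened")
    (out / "screen.json").write_text(
        json.dumps(
            {
                "q": config.q,
                "retained": screen.retained,
                "pvalues": {k: float(v) for k, v in screen.pvalues.items()},
            },
            indent=2,
        )
    )
    manifest["stages"]["screen"] = {"retained": len(screen.retained)}

    df = cohort.merge(
        fm.data.rename_axis("patient_id").reset_index(), on="patient_id"
    )
    feature_cols = list(fm.data.columns)

    try:
        res = estimate_all(
            df, feature_cols, horizons=config.horizons, folds=config.folds,
            gamma=config.gamma, n_lambdas=config.n_lambdas,
            interval_days=config.interval_days, seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError("estimate", "estimation_failed", str(exc)) from exc

    res["ps_fit"].to_json(out / "propensity.json")
    weights = iptw_weights(df["arm"].to_numpy(int), res["ps"])
    balance = smd_balance(df[feature_cols], df["arm"].to_numpy(int), weights)
    balance.rename_axis("feature").to_csv(out / "balance.csv")

    curves = []
    for a in (0, 1):
        sub = df[df["arm"] == a]
        km = km_curve(
            sub["time_to_relapse_days"].to_numpy(), sub["event_indicator"].to_numpy()
        )
        km["arm"], km["kind"] = a, "crude_km"
        curves.append(km)
    dr_curves = dr_incidence_curves(
        df, res["surv_models"], feature_cols, config.horizons[-1],
        config.interval_days,
    )
    dr_curves["kind"] = "dr_adjusted"
    pd.concat(curves + [dr_curves], ignore_index=True).to_csv(
        out / "curves.csv", index=False
    )

    est = res["estimates"]
    (out / "estimates.json").write_text(
        json.dumps(
            {
                k: {
                    "point": e.contrast, "mu1": e.mu1, "mu0": e.mu0,
                    "se": e.se, "n1": e.n1, "n0": e.n0, "flags": e.flags,
                }
                for k, e in est.items()
            },
            indent=2,
        )
    )
    manifest["stages"]["estimate"] = {k: est[k].contrast for k in est}

    def point_pipeline(d: pd.DataFrame) -> dict[str, float]:
        r = estimate_all(
            d, feature_cols, horizons=config.horizons, folds=config.folds,
            gamma=config.gamma, n_lambdas=config.n_lambdas,
            interval_days=config.interval_days, seed=config.seed,
        )
        return {k: v.contrast for k, v in r["estimates"].items()}

    try:
        summaries = bootstrap_estimates(
            point_pipeline, df, B=config.B, seed=config.seed + 1,
        )
    except Exception as exc:
        raise PipelineError("bootstrap", "bootstrap_failed", str(exc)) from exc

    report = {"comparison": {"drug_a": config.drug_a, "drug_b": config.drug_b,
                             "tier": config.tier, "reference": config.drug_a},
              "B": config.B, "seed": config.seed, "estimands": {}}
    for name, s in summaries.items():
        entry = {
            "estimate": s.point,
            "ci95": list(s.ci),
            "p_raw": s.p_raw,
            "p_adjusted": s.p_adjusted,
        }
        significant = (
            s.p_adjusted if s.p_adjusted is not None else 1.0
        ) < 0.05
        if significant:
            if name == "rr_nonrelapse":
                ev = evalue_rr(s.point, s.ci)
            else:
                e = est[name]
                ev = evalue_rd(
                    float(np.clip(e.mu1, 1e-6, 1 - 1e-6)),
                    float(np.clip(e.mu0, 1e-6, 1 - 1e-6)),
                )
            entry["E"], entry["E_star"], entry["evalue_formula"] = ev.E, ev.E_star, ev.formula
        else:
            entry["E"] = entry["E_star"] = None
        report["estimands"][name] = entry
    (out / "report.json").write_text(json.dumps(report, indent=2))
    manifest["stages"]["report"] = {
        k: report["estimands"][k]["p_adjusted"] for k in report["estimands"]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return report
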
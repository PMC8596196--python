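"""Eligibility, treatment-arm assignment and relapse-outcome derivation.

Two assignment rules mirror common prescription patterns for MS DMTs:

* standard-efficacy comparison — arm is the first episode of either study
  drug; any higher-efficacy or chemotherapy exposure before that index
  date excludes the patient;
* higher-efficacy comparison — arm is the first-ever higher-efficacy DMT
  (whether started directly or switched to from a standard-efficacy DMT),
  provided it is one of the two study drugs; chemotherapy preceding the
  index date excludes the patient.

Three relapse outcomes are derived per assigned patient: relapse by 1 year,
relapse by 2 years (each possibly missing due to censoring before the
horizon) and time to first relapse with an event indicator. Clinical and
radiologic relapses count identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: drug -> efficacy tier
DRUG_TIERS: dict[str, str] = {
    "interferon-beta": "standard",
    "glatiramer acetate": "standard",
    "daclizumab": "standard",
    "dimethyl fumarate": "standard",
    "fingolimod": "standard",
    "teriflunomide": "standard",
    "natalizumab": "higher",
    "rituximab": "higher",
    "alemtuzumab": "higher",
    "cyclophosphamide": "chemo",
    "mitoxantrone": "chemo",
}


class DataError(ValueError):
    """Malformed input records."""


@dataclass(frozen=True)
class DMTEpisode:
    """One treatment episode. ``end_day`` is None while the episode is open."""

    patient_id: int
    drug: str
    start_day: int
    end_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.drug not in DRUG_TIERS:
            raise DataError(f"unknown DMT {self.drug!r}")
        if self.end_day is not None and self.start_day > self.end_day:
            raise DataError("episode start_day after end_day")

    @property
    def tier(self) -> str:
        return DRUG_TIERS[self.drug]


@dataclass
class OutcomeRecord:
    """Derived relapse outcomes for one patient.

    Horizon indicators are None when the patient is censored before the
    horizon without a prior relapse (missing, to be handled by IPCW
    downstream).
    """

    relapse_1y: Optional[int]
    relapse_2y: Optional[int]
    time_to_relapse_days: int
    event_indicator: int


def _sorted(episodes: Iterable[DMTEpisode]) -> list[DMTEpisode]:
    return sorted(episodes, key=lambda e: (e.start_day, e.drug))


def assign_arm_standard(
    episodes: Iterable[DMTEpisode], drug_a: str, drug_b: str
) -> Optional[tuple[str, int]]:
    """Standard-efficacy arm assignment.

    Returns ``(drug, index_day)`` for the first episode of either study
    drug, or None (excluded) if there is no such episode or the patient
    received any higher-efficacy or chemotherapy DMT before that index
    date. Insensitive to input ordering.
    """
    for d in (drug_a, drug_b):
        if DRUG_TIERS.get(d) != "standard":
            raise DataError(f"{d!r} is not a standard-efficacy DMT")
    eps = _sorted(episodes)
    index = next((e for e in eps if e.drug in (drug_a, drug_b)), None)
    if index is None:
        return None
    prior_high = any(
        e.tier in ("higher", "chemo") and e.start_day < index.start_day for e in eps
    )
    if prior_high:
        return None
    return index.drug, index.start_day


def assign_arm_higher(
    episodes: Iterable[DMTEpisode], drug_a: str, drug_b: str
) -> Optional[tuple[str, int]]:
    """Higher-efficacy arm assignment.

    The index episode is the first-ever higher-efficacy DMT episode
    (covering both direct starters and patients switching from a
    standard-efficacy DMT). The patient is assigned to its drug if it is
    one of the two study drugs, and excluded otherwise or if chemotherapy
    preceded the index date.
    """
    for d in (drug_a, drug_b):
        if DRUG_TIERS.get(d) != "higher":
            raise DataError(f"{d!r} is not a higher-efficacy DMT")
    eps = _sorted(episodes)
    index = next((e for e in eps if e.tier == "higher"), None)
    if index is None:
        return None
    if any(e.tier == "chemo" and e.start_day < index.start_day for e in eps):
        return None
    if index.drug not in (drug_a, drug_b):
        return None
    return index.drug, index.start_day


def derive_outcomes(
    relapse_days: Sequence[int],
    censor_day: int,
    horizons: Sequence[int] = (365, 730),
    include_index_day: bool = False,
) -> OutcomeRecord:
    """Derive the three relapse outcomes from post-index relapse days.

    ``relapse_days`` are days after the index date; ``censor_day`` is the
    end of follow-up in the same units. Relapses on the index day itself
    are ignored unless ``include_index_day`` is set; relapses recorded
    after the censoring day are ignored. Horizon intervals are half-open
    ``(0, h]``.
    """
    if censor_day < 0:
        raise DataError("censor_day must be nonnegative")
    days = sorted(int(d) for d in relapse_days)
    if days and days[0] < 0:
        raise DataError("negative relapse day")
    floor = -1 if include_index_day else 0
    days = [d for d in days if floor < d <= censor_day]
    if days:
        time, event = days[0], 1
    else:
        time, event = censor_day, 0

    def indicator(h: int) -> Optional[int]:
        if event and time <= h:
            return 1
        if censor_day >= h:
            return 0
        return None

    h1, h2 = horizons[0], horizons[-1]
    return OutcomeRecord(
        relapse_1y=indicator(h1),
        relapse_2y=indicator(h2),
        time_to_relapse_days=int(time),
        event_indicator=event,
    )


def assemble_cohort(
    patients: pd.DataFrame,
    episodes: pd.DataFrame,
    relapses: pd.DataFrame,
    drug_a: str,
    drug_b: str,
    tier: str = "standard",
    horizons: Sequence[int] = (365, 730),
    include_index_day: bool = False,
) -> pd.DataFrame:
    """Apply arm assignment and outcome derivation over tabular inputs.

    ``patients`` must carry patient_id and censor_day (absolute);
    ``episodes`` patient_id/drug/start_day/end_day; ``relapses``
    patient_id/day (absolute). Returns one row per assigned patient with
    arm (0 = drug_a, 1 = drug_b), index_day and the outcome columns;
    excluded patients are dropped.
    """
    if tier not in ("standard", "higher"):
        raise DataError("tier must be 'standard' or 'higher'")
    assign = assign_arm_standard if tier == "standard" else assign_arm_higher
    ep_by_pat = {
        pid: [
            DMTEpisode(
                patient_id=pid,
                drug=r.drug,
                start_day=int(r.start_day),
                end_day=None if pd.isna(r.end_day) else int(r.end_day),
            )
            for r in grp.itertuples()
        ]
        for pid, grp in episodes.groupby("patient_id")
    }
    rel_by_pat = {pid: grp["day"].to_numpy() for pid, grp in relapses.groupby("patient_id")}
    censor = patients.set_index("patient_id")["censor_day"]

    rows = []
    for pid, eps in ep_by_pat.items():
        assigned = assign(eps, drug_a, drug_b)
        if assigned is None or pid not in censor.index:
            continue
        drug, index_day = assigned
        censor_rel = int(censor.loc[pid]) - index_day
        if censor_rel <= 0:
            continue
        rel_days = rel_by_pat.get(pid, np.empty(0, dtype=int)) - index_day
        rel_days = rel_days[rel_days >= 0]
        rec = derive_outcomes(
            rel_days.tolist(), censor_rel, horizons, include_index_day
        )
        rows.append(
            {
                "patient_id": pid,
                "arm": 0 if drug == drug_a else 1,
                "drug": drug,
                "index_day": index_day,
                "censor_rel_day": censor_rel,
                "relapse_1y": rec.relapse_1y,
                "relapse_2y": rec.relapse_2y,
                "time_to_relapse_days": rec.time_to_relapse_days,
                "event_indicator": rec.event_indicator,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["relapse_1y"] = out["relapse_1y"].astype("Float64")
        out["relapse_2y"] = out["relapse_2y"].astype("Float64")
    return out
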
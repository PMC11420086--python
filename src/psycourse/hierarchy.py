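"""Hierarchical diagnostic endpoints and progression to schizophrenia.

The four major psychotic diagnoses are ranked by clinical severity —
schizophrenia (1) > schizoaffective disorder (2) > bipolar disorder (3) >
psychotic MDD (4). Each person's event stream yields:

* ``onset_date`` — first registry-recorded diagnosis indicating a psychotic
  illness (time zero for the burden metric);
* ``first_major`` — earliest of the four ranked diagnoses (same-day ties go
  to the more severe class);
* ``main_lifetime`` — the most severe class ever recorded;
* a progression record: the hierarchy is unidirectional, so progression means
  a first schizophrenia diagnosis strictly after a lower-ranked first major
  diagnosis. Shifts among the lower tiers are not labelled progression.
"""
from __future__ import annotations

import dataclasses
import datetime
from typing import Iterable

import numpy as np
import pandas as pd

from .registry import DiagnosisEvent, MajorClass, RegistryBundle, classify_codes

DAYS_PER_YEAR = 365.25

#: Severity ranks; 1 = most severe.
RANKS: dict[MajorClass, int] = {
    MajorClass.SZ: 1,
    MajorClass.SAD: 2,
    MajorClass.BD: 3,
    MajorClass.PMDD: 4,
}
_CLASS_BY_RANK = {v: k for k, v in RANKS.items()}


def rank_of(major_class: MajorClass | str) -> int:
    """Severity rank of a major class (SZ→1 … pMDD→4)."""
    mc = MajorClass(major_class)
    if mc not in RANKS:
        raise ValueError(f"{mc} has no severity rank")
    return RANKS[mc]


TRAJECTORY_COLUMNS = [
    "person_id", "onset_date", "onset_age", "first_major", "first_major_date",
    "main_lifetime", "progressed_to_sz", "from_class", "sz_date", "delay_years",
    "time_at_risk_years", "sud", "sud_date",
]


@dataclasses.dataclass(frozen=True)
class ProgressionRecord:
    progressed_to_sz: bool
    from_class: MajorClass | None = None
    sz_date: datetime.date | None = None
    delay_years: float | None = None
    time_at_risk_years: float | None = None


@dataclasses.dataclass(frozen=True)
class TrajectorySummary:
    person_id: str
    onset_date: datetime.date | None
    onset_age: float | None
    first_major: MajorClass
    first_major_date: datetime.date | None
    main_lifetime: MajorClass
    progression: ProgressionRecord
    sud: bool
    sud_date: datetime.date | None


def summarize_trajectories(
    bundle: RegistryBundle,
    time_origin: str = "first_major",
) -> pd.DataFrame:
    """Per-person trajectory table for a whole bundle (vectorized).

    ``time_origin`` controls the start of the progression time-at-risk clock:
    ``"first_major"`` (default) or ``"onset"``.
    """
    if time_origin not in ("first_major", "onset"):
        raise ValueError("time_origin must be 'first_major' or 'onset'")
    persons = bundle.persons[["person_id", "birth_date"]].copy()
    end = pd.Timestamp(bundle.study_end)

    dx = bundle.diagnoses.copy()
    if len(dx):
        flags = classify_codes(dx["code"], dx["icd_version"])
        dx = pd.concat([dx.reset_index(drop=True), flags.reset_index(drop=True)], axis=1)
        dx["date"] = pd.to_datetime(dx["date"])

    def first_date(mask: pd.Series) -> pd.Series:
        sub = dx.loc[mask]
        return sub.groupby("person_id")["date"].min()

    out = persons.set_index("person_id")
    out["birth_date"] = pd.to_datetime(out["birth_date"])
    if len(dx):
        out["onset_date"] = first_date(dx["is_psychosis"])
        # first major: earliest date, severity-first tie break
        major = dx.loc[dx["major_class"] != MajorClass.NONE.value].copy()
        if len(major):
            major["rank"] = major["major_class"].map(lambda c: RANKS[MajorClass(c)])
            major = major.sort_values(["person_id", "date", "rank"], kind="mergesort")
            fm = major.groupby("person_id").first()
            out["first_major"] = fm["major_class"]
            out["first_major_date"] = fm["date"]
            best = major.groupby("person_id")["rank"].min()
            out["main_lifetime"] = best.map(lambda r: _CLASS_BY_RANK[r].value)
            out["sz_date"] = first_date(dx["major_class"] == MajorClass.SZ.value)
        out["sud_date"] = first_date(dx["is_sud"])

    for col in ("onset_date", "first_major_date", "sz_date", "sud_date"):
        if col not in out.columns:
            out[col] = pd.NaT
        out[col] = pd.to_datetime(out[col])
    for col, default in (("first_major", MajorClass.NONE.value), ("main_lifetime", MajorClass.NONE.value)):
        if col not in out.columns:
            out[col] = default
        out[col] = out[col].fillna(default)

    out["onset_age"] = (out["onset_date"] - out["birth_date"]).dt.days / DAYS_PER_YEAR
    out["sud"] = out["sud_date"].notna()

    has_major = out["first_major"] != MajorClass.NONE.value
    progressed = has_major & (out["first_major"] != MajorClass.SZ.value) & out["sz_date"].notna()
    out["progressed_to_sz"] = progressed
    out["from_class"] = np.where(progressed, out["first_major"], MajorClass.NONE.value)

    origin = out["first_major_date"] if time_origin == "first_major" else out["onset_date"]
    stop = out["sz_date"].fillna(end)
    out["delay_years"] = np.where(
        progressed, (out["sz_date"] - out["first_major_date"]).dt.days / DAYS_PER_YEAR, np.nan
    )
    at_risk = (stop - origin).dt.days / DAYS_PER_YEAR
    out["time_at_risk_years"] = np.where(has_major, at_risk, np.nan)

    out = out.reset_index()
    return out[TRAJECTORY_COLUMNS]


def summarize_trajectory(
    events: Iterable[DiagnosisEvent] | pd.DataFrame,
    study_end: datetime.date,
    birth_date: datetime.date | None = None,
    person_id: str = "p0",
) -> TrajectorySummary:
    """Single-person convenience wrapper around :func:`summarize_trajectories`.

    An empty event stream yields an all-``none`` summary, not an error.
    """
    from .registry import N_PCS, PGS_TRAITS

    if isinstance(events, pd.DataFrame):
        dx = events.copy()
    else:
        dx = pd.DataFrame(
            [
                {"person_id": person_id, "date": e.date, "icd_version": e.icd_version, "code": e.code}
                for e in events
            ],
            columns=["person_id", "date", "icd_version", "code"],
        )
    if len(dx):
        dx["person_id"] = person_id
    person_row = {
        "person_id": person_id,
        "sex": "female",
        "birth_date": birth_date or datetime.date(1970, 1, 1),
        **{f"pgs_{t}": 0.0 for t in PGS_TRAITS},
        **{f"pc{i}": 0.0 for i in range(1, N_PCS + 1)},
    }
    bundle = RegistryBundle(
        persons=pd.DataFrame([person_row]),
        diagnoses=dx,
        episodes=pd.DataFrame(columns=["person_id", "admit_date", "discharge_date", "primary_code"]),
        study_end=study_end,
    )
    row = summarize_trajectories(bundle).iloc[0]

    def to_date(v):
        return None if pd.isna(v) else pd.Timestamp(v).date()

    return TrajectorySummary(
        person_id=person_id,
        onset_date=to_date(row["onset_date"]),
        onset_age=None if pd.isna(row["onset_age"]) else float(row["onset_age"]),
        first_major=MajorClass(row["first_major"]),
        first_major_date=to_date(row["first_major_date"]),
        main_lifetime=MajorClass(row["main_lifetime"]),
        progression=ProgressionRecord(
            progressed_to_sz=bool(row["progressed_to_sz"]),
            from_class=None if row["from_class"] == "none" else MajorClass(row["from_class"]),
            sz_date=to_date(row["sz_date"]),
            delay_years=None if pd.isna(row["delay_years"]) else float(row["delay_years"]),
            time_at_risk_years=None
            if pd.isna(row["time_at_risk_years"])
            else float(row["time_at_risk_years"]),
        ),
        sud=bool(row["sud"]),
        sud_date=to_date(row["sud_date"]),
    )


PROGRESSION_GROUPS = (
    "direct_sz", "progressed_to_sz", "remained_SAD", "remained_BD", "remained_pMDD",
)


def progression_cohort(trajectories: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition persons with ≥1 major diagnosis into progression groups.

    Groups: ``direct_sz`` (schizophrenia first), ``progressed_to_sz`` (lower
    first major, schizophrenia later), ``remained_<class>`` (never reached
    schizophrenia). Returns the labelled sub-table and the group counts.
    """
    traj = trajectories.loc[trajectories["first_major"] != MajorClass.NONE.value].copy()
    group = np.where(
        traj["first_major"] == MajorClass.SZ.value,
        "direct_sz",
        np.where(
            traj["progressed_to_sz"],
            "progressed_to_sz",
            "remained_" + traj["first_major"].astype(str),
        ),
    )
    traj["progression_group"] = group
    counts = {g: int((traj["progression_group"] == g).sum()) for g in PROGRESSION_GROUPS}
    return traj, counts
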
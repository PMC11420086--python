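"""Onset-aligned psychiatric hospitalization burden and hospital usage profiles.

The burden metric tracks disease-course severity: each person's timeline is
aligned so their first psychosis-indicating diagnosis is time zero, the first
15 aligned years (365.25-day bins) are scanned for hospitalizations whose
primary discharge diagnosis is psychiatric, and the burden is the fraction of
observed aligned years with at least one such admission. Aligned-year bins
rather than calendar years keep year 0 the same length for everyone
regardless of onset month.

Usage profiles decompose the same 15-year window into episode count, total
length of stay and median per-episode length of stay — separating a
"revolving door" pattern (short, frequent stays) from long continuous care.
"""
from __future__ import annotations

import dataclasses
import datetime
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .registry import HospitalEpisode, RegistryBundle, classify_codes

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_WINDOW_YEARS = 15

BURDEN_COLUMNS = ["person_id", "observed_years", "burden_fraction"] + [
    f"y{k}" for k in range(DEFAULT_WINDOW_YEARS)
]
USAGE_COLUMNS = ["person_id", "n_episodes", "total_los_days", "median_los_days"]


class NoOnsetError(ValueError):
    """Raised when a burden computation is requested without a psychosis onset."""


@dataclasses.dataclass(frozen=True)
class BurdenSeries:
    person_id: str
    indicators: tuple[bool, ...]      # one per aligned year 0..window-1
    observed_years: int               # censoring-aware denominator, ≤ window
    burden_fraction: float


@dataclasses.dataclass(frozen=True)
class UsageProfile:
    person_id: str
    n_episodes: int
    total_los_days: int
    median_los_days: float | None     # undefined when n_episodes == 0


# ---------------------------------------------------------------------------
# Per-person computations
# ---------------------------------------------------------------------------

def _episode_day_offsets(
    episodes: Sequence[HospitalEpisode] | pd.DataFrame, onset_date: datetime.date
) -> tuple[np.ndarray, np.ndarray]:
    """Start/end day offsets (inclusive, onset = day 0) for each episode."""
    if isinstance(episodes, pd.DataFrame):
        admit = pd.to_datetime(episodes["admit_date"])
        disch = pd.to_datetime(episodes["discharge_date"])
        onset = pd.Timestamp(onset_date)
        return (admit - onset).dt.days.to_numpy(), (disch - onset).dt.days.to_numpy()
    starts = np.array([(e.admit_date - onset_date).days for e in episodes], dtype=int)
    ends = np.array([(e.discharge_date - onset_date).days for e in episodes], dtype=int)
    return starts, ends


def observed_years_for(
    onset_date: datetime.date, study_end: datetime.date, window_years: int = DEFAULT_WINDOW_YEARS
) -> int:
    """Number of aligned years under observation before administrative censoring."""
    follow_days = (study_end - onset_date).days
    return int(min(window_years, int(np.ceil(follow_days / DAYS_PER_YEAR))))


def yearly_indicators(
    episodes: Sequence[HospitalEpisode] | pd.DataFrame,
    onset_date: datetime.date | None,
    study_end: datetime.date,
    window_years: int = DEFAULT_WINDOW_YEARS,
    person_id: str = "p0",
) -> BurdenSeries:
    """Aligned-year hospitalization indicators and the burden fraction.

    ``episodes`` must already be filtered to psychiatric-primary admissions.
    Aligned year ``k`` covers day offsets ``[k*365.25, (k+1)*365.25)``; an
    episode marks every aligned year it overlaps. Persons with less than one
    observed year raise :class:`NoOnsetError`-adjacent exclusion (ValueError).
    """
    if onset_date is None or pd.isna(onset_date):
        raise NoOnsetError(f"person {person_id}: no psychosis onset date")
    observed = observed_years_for(onset_date, study_end, window_years)
    if observed < 1:
        raise ValueError(f"person {person_id}: less than one observed year after onset")

    marked = np.zeros(window_years, dtype=bool)
    starts, ends = _episode_day_offsets(episodes, onset_date)
    for s, e in zip(starts, ends):
        k_lo = max(0, int(np.floor(s / DAYS_PER_YEAR)))
        k_hi = min(observed - 1, int(np.floor(e / DAYS_PER_YEAR)))
        if e < 0 or k_lo > k_hi:
            continue
        marked[k_lo : k_hi + 1] = True
    fraction = float(marked[:observed].sum() / observed)
    return BurdenSeries(
        person_id=person_id,
        indicators=tuple(bool(v) for v in marked),
        observed_years=observed,
        burden_fraction=fraction,
    )


def usage_profile(
    episodes: Sequence[HospitalEpisode] | pd.DataFrame,
    onset_date: datetime.date | None,
    window_years: int = DEFAULT_WINDOW_YEARS,
    person_id: str = "p0",
) -> UsageProfile:
    """Episode count, total and median length of stay within the aligned window.

    Episodes are clipped to ``[onset, onset + window*365.25)`` before summing;
    length of stay counts both admission and discharge day.
    """
    if onset_date is None or pd.isna(onset_date):
        raise NoOnsetError(f"person {person_id}: no psychosis onset date")
    window_days = int(np.floor(window_years * DAYS_PER_YEAR))  # day offsets 0..window_days-1... inclusive end below
    starts, ends = _episode_day_offsets(episodes, onset_date)
    last_day = int(np.ceil(window_years * DAYS_PER_YEAR)) - 1
    s = np.maximum(starts, 0)
    e = np.minimum(ends, last_day)
    los = e - s + 1
    los = los[(ends >= 0) & (starts <= last_day) & (los > 0)]
    n = int(los.size)
    return UsageProfile(
        person_id=person_id,
        n_episodes=n,
        total_los_days=int(los.sum()) if n else 0,
        median_los_days=float(np.median(los)) if n else None,
    )


# ---------------------------------------------------------------------------
# Cohort-level computations
# ---------------------------------------------------------------------------

def _psychiatric_episodes(bundle: RegistryBundle) -> pd.DataFrame:
    ep = bundle.episodes
    if not len(ep):
        return ep
    flags = classify_codes(ep["primary_code"], 10)
    return ep.loc[flags["is_psychiatric_primary"].to_numpy()].reset_index(drop=True)


def cohort_burden(
    bundle: RegistryBundle,
    trajectories: pd.DataFrame,
    window_years: int = DEFAULT_WINDOW_YEARS,
) -> pd.DataFrame:
    """Burden table (person_id, observed_years, burden_fraction, y0..y14).

    Persons without a psychosis onset, or with under one observed year, are
    excluded (counted in the log). Episode filtering to psychiatric-primary
    admissions happens here.
    """
    ep = _psychiatric_episodes(bundle)
    traj = trajectories.set_index("person_id")
    onset = pd.to_datetime(traj["onset_date"])
    end = pd.Timestamp(bundle.study_end)

    follow = (end - onset).dt.days
    observed = np.minimum(window_years, np.ceil(follow / DAYS_PER_YEAR)).astype("float")
    keep = onset.notna() & (observed >= 1)
    n_no_onset = int(onset.isna().sum())
    n_short = int((onset.notna() & (observed < 1)).sum())
    if n_no_onset or n_short:
        logger.info(
            "burden: excluded %d persons without onset and %d with <1 observed year",
            n_no_onset, n_short,
        )
    idx = traj.index[keep]
    observed = observed.loc[idx].astype(int)

    marks = pd.DataFrame(
        False, index=idx, columns=[f"y{k}" for k in range(window_years)]
    )
    if len(ep):
        ep = ep.loc[ep["person_id"].isin(idx)].copy()
        ep_onset = onset.loc[ep["person_id"]].to_numpy()
        s = (pd.to_datetime(ep["admit_date"]).to_numpy() - ep_onset) / np.timedelta64(1, "D")
        e = (pd.to_datetime(ep["discharge_date"]).to_numpy() - ep_onset) / np.timedelta64(1, "D")
        k_lo = np.maximum(0, np.floor(s / DAYS_PER_YEAR)).astype(int)
        k_hi = np.floor(e / DAYS_PER_YEAR).astype(int)
        obs_per_ep = observed.loc[ep["person_id"]].to_numpy()
        k_hi = np.minimum(k_hi, obs_per_ep - 1)
        valid = (e >= 0) & (k_lo <= k_hi)
        pid = ep["person_id"].to_numpy()
        max_span = int((k_hi[valid] - k_lo[valid]).max()) if valid.any() else -1
        pos = {p: i for i, p in enumerate(idx)}
        arr = marks.to_numpy()
        for d in range(max_span + 1):
            sel = valid & (k_lo + d <= k_hi)
            rows = np.fromiter((pos[p] for p in pid[sel]), dtype=int, count=int(sel.sum()))
            arr[rows, k_lo[sel] + d] = True
        marks.loc[:, :] = arr

    # indicators beyond the observed horizon stay False
    year_grid = np.arange(window_years)[None, :]
    in_obs = year_grid < observed.to_numpy()[:, None]
    counted = marks.to_numpy() & in_obs
    out = pd.DataFrame(
        {
            "person_id": idx,
            "observed_years": observed.to_numpy(),
            "burden_fraction": counted.sum(axis=1) / observed.to_numpy(),
        }
    )
    for k in range(window_years):
        out[f"y{k}"] = counted[:, k].astype(int)
    return out.reset_index(drop=True)


def window_episode_lengths(
    bundle: RegistryBundle,
    trajectories: pd.DataFrame,
    window_years: int = DEFAULT_WINDOW_YEARS,
) -> pd.DataFrame:
    """Clipped per-episode lengths of stay inside the onset-aligned window.

    Returns one row per psychiatric-primary episode overlapping the window:
    ``person_id``, ``los`` (days, clipped to the window, inclusive of both
    admission and discharge day).
    """
    ep = _psychiatric_episodes(bundle)
    traj = trajectories.set_index("person_id")
    onset = pd.to_datetime(traj["onset_date"])
    idx = traj.index[onset.notna()]
    last_day = int(np.ceil(window_years * DAYS_PER_YEAR)) - 1
    if not len(ep):
        return pd.DataFrame(columns=["person_id", "los"])
    ep = ep.loc[ep["person_id"].isin(idx)].copy()
    ep_onset = onset.loc[ep["person_id"]].to_numpy()
    s = ((pd.to_datetime(ep["admit_date"]).to_numpy() - ep_onset) / np.timedelta64(1, "D")).astype(int)
    e = ((pd.to_datetime(ep["discharge_date"]).to_numpy() - ep_onset) / np.timedelta64(1, "D")).astype(int)
    clip_s = np.maximum(s, 0)
    clip_e = np.minimum(e, last_day)
    los = clip_e - clip_s + 1
    ok = (e >= 0) & (s <= last_day) & (los > 0)
    return pd.DataFrame({"person_id": ep["person_id"].to_numpy()[ok], "los": los[ok]})


def cohort_usage(
    bundle: RegistryBundle,
    trajectories: pd.DataFrame,
    window_years: int = DEFAULT_WINDOW_YEARS,
) -> pd.DataFrame:
    """Usage table (person_id, n_episodes, total_los_days, median_los_days)."""
    traj = trajectories.set_index("person_id")
    onset = pd.to_datetime(traj["onset_date"])
    idx = traj.index[onset.notna()]

    per = window_episode_lengths(bundle, trajectories, window_years)
    if len(per):
        grouped = per.groupby("person_id")["los"]
        stats = pd.DataFrame(
            {"n_episodes": grouped.size(), "total_los_days": grouped.sum(), "median_los_days": grouped.median()}
        )
    else:
        stats = pd.DataFrame(columns=["n_episodes", "total_los_days", "median_los_days"])

    out = pd.DataFrame(index=idx).join(stats)
    out["n_episodes"] = out["n_episodes"].fillna(0).astype(int)
    out["total_los_days"] = out["total_los_days"].fillna(0).astype(int)
    out = out.reset_index().rename(columns={"index": "person_id"})
    if "person_id" not in out.columns:  # pandas names the index column automatically
        out = out.rename(columns={out.columns[0]: "person_id"})
    return out[USAGE_COLUMNS]


# ---------------------------------------------------------------------------
# Rank-based inverse-normal transform
# ---------------------------------------------------------------------------

def int_transform(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    Maps value of rank ``r`` (average ranks for ties) among ``n`` to
    ``Φ⁻¹((r − 3/8) / (n + 1/4))``, giving an SD-scale outcome robust to the
    skew and coarseness of fraction-type variables.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("int_transform needs a 1-D array with n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("int_transform requires finite values")
    if np.all(x == x[0]):
        raise ValueError("int_transform undefined for constant input")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 3.0 / 8.0) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# Group curves
# ---------------------------------------------------------------------------

def group_burden_curve(
    burden: pd.DataFrame,
    groups: pd.Series,
    axis: str = "aligned_year",
    window_years: int = DEFAULT_WINDOW_YEARS,
) -> pd.DataFrame:
    """Proportion hospitalized per group per aligned year.

    ``groups`` maps person_id → group label. Empty groups are omitted with a
    warning. Output columns: group, unit, n_observed, n_hospitalized,
    proportion.
    """
    if axis != "aligned_year":
        raise ValueError("supported axes: 'aligned_year' (use age_burden_curve for age)")
    df = burden.set_index("person_id")
    groups = groups.reindex(df.index)
    records = []
    for label, sub in df.groupby(groups):
        if not len(sub):
            continue
        for k in range(window_years):
            observed = sub["observed_years"] > k
            n_obs = int(observed.sum())
            if n_obs == 0:
                continue
            n_hosp = int(sub.loc[observed, f"y{k}"].sum())
            records.append(
                {"group": label, "unit": k, "n_observed": n_obs,
                 "n_hospitalized": n_hosp, "proportion": n_hosp / n_obs}
            )
    missing = set(groups.dropna().unique()) - {r["group"] for r in records}
    for g in missing:
        logger.warning("group_burden_curve: group %r empty, omitted", g)
    return pd.DataFrame.from_records(records, columns=["group", "unit", "n_observed", "n_hospitalized", "proportion"])


def age_burden_curve(
    bundle: RegistryBundle,
    groups: pd.Series,
    age_range: tuple[int, int] = (18, 70),
) -> pd.DataFrame:
    """Proportion hospitalized (psychiatric-primary) per group per age year.

    Age years are 365.25-day bins from birth. A person contributes to the
    denominator at age ``a`` when that whole age-year lies within the
    registry's coverage (1969-01-01 .. study_end).
    """
    from .registry import REGISTRY_START

    ep = _psychiatric_episodes(bundle)
    persons = bundle.persons.set_index("person_id")
    birth = pd.to_datetime(persons["birth_date"])
    start = pd.Timestamp(REGISTRY_START)
    end = pd.Timestamp(bundle.study_end)
    lo_age = ((start - birth).dt.days / DAYS_PER_YEAR).clip(lower=0)
    hi_age = (end - birth).dt.days / DAYS_PER_YEAR

    hosp: dict[tuple[str, int], bool] = {}
    if len(ep):
        b = birth.loc[ep["person_id"]].to_numpy()
        s = (pd.to_datetime(ep["admit_date"]).to_numpy() - b) / np.timedelta64(1, "D")
        e = (pd.to_datetime(ep["discharge_date"]).to_numpy() - b) / np.timedelta64(1, "D")
        a_lo = np.floor(s / DAYS_PER_YEAR).astype(int)
        a_hi = np.floor(e / DAYS_PER_YEAR).astype(int)
        for pid, lo, hi in zip(ep["person_id"], a_lo, a_hi):
            for a in range(lo, hi + 1):
                hosp[(pid, a)] = True

    groups = groups.reindex(persons.index)
    records = []
    for label, ids in persons.groupby(groups).groups.items():
        for a in range(age_range[0], age_range[1] + 1):
            observed = [
                pid for pid in ids
                if lo_age.loc[pid] <= a and (a + 1) <= hi_age.loc[pid]
            ]
            if not observed:
                continue
            n_hosp = sum(hosp.get((pid, a), False) for pid in observed)
            records.append(
                {"group": label, "unit": a, "n_observed": len(observed),
                 "n_hospitalized": n_hosp, "proportion": n_hosp / len(observed)}
            )
    return pd.DataFrame.from_records(records, columns=["group", "unit", "n_observed", "n_hospitalized", "proportion"])
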
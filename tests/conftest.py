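import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from psycourse.registry import N_PCS, PGS_TRAITS, RegistryBundle

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def person_row(pid="p1", sex="female", birth="1970-01-01", **pgs):
    row = {"person_id": pid, "sex": sex, "birth_date": birth}
    for t in PGS_TRAITS:
        row[f"pgs_{t}"] = float(pgs.get(t, 0.0))
    for i in range(1, N_PCS + 1):
        row[f"pc{i}"] = 0.0
    return row


def make_bundle(persons, diagnoses=(), episodes=(), study_end=datetime.date(2018, 12, 31)):
    """Small hand-built registry bundle.

    ``persons``: list of person_row dicts; ``diagnoses``: (pid, date, code)
    triples; ``episodes``: (pid, admit, discharge, code) quadruples.
    """
    pf = pd.DataFrame(persons)
    pf["birth_date"] = pd.to_datetime(pf["birth_date"])
    df = pd.DataFrame(
        [{"person_id": p, "date": d, "icd_version": 10, "code": c} for p, d, c in diagnoses],
        columns=["person_id", "date", "icd_version", "code"],
    )
    df["date"] = pd.to_datetime(df["date"])
    ef = pd.DataFrame(
        [
            {"person_id": p, "admit_date": a, "discharge_date": b, "primary_code": c}
            for p, a, b, c in episodes
        ],
        columns=["person_id", "admit_date", "discharge_date", "primary_code"],
    )
    for c in ("admit_date", "discharge_date"):
        ef[c] = pd.to_datetime(ef[c])
    return RegistryBundle(persons=pf, diagnoses=df, episodes=ef, study_end=study_end)


def brute_force_burden(episode_spans, onset, study_end, window=15):
    """Day-level enumeration oracle for the burden metric.

    Walks every single day of the aligned window, marks the aligned year
    (floor(day/365.25)) whenever the day falls inside any episode, and counts
    observed years by ceiling division — entirely independent of the
    vectorized implementation.
    """
    follow = (study_end - onset).days
    observed = min(window, int(np.ceil(follow / 365.25)))
    marked = [False] * window
    last_day = int(np.ceil(window * 365.25)) - 1
    for admit, discharge in episode_spans:
        d = admit
        while d <= discharge:
            off = (d - onset).days
            if 0 <= off <= last_day:
                year = int(off // 365.25)
                if year < observed:
                    marked[year] = True
            d += datetime.timedelta(days=1)
    fraction = sum(marked[:observed]) / observed
    return marked, observed, fraction


def brute_force_usage(episode_spans, onset, window=15):
    """Day-level oracle for episode counts / total / median length of stay."""
    last_day = int(np.ceil(window * 365.25)) - 1
    lengths = []
    for admit, discharge in episode_spans:
        days = [
            d
            for d in range((admit - onset).days, (discharge - onset).days + 1)
            if 0 <= d <= last_day
        ]
        if days:
            lengths.append(len(days))
    total = sum(lengths)
    median = float(np.median(lengths)) if lengths else None
    return len(lengths), total, median


@pytest.fixture(scope="session")
def small_full_bundle():
    from psycourse.simulate import preset_paper_defaults, simulate_cohort

    preset = preset_paper_defaults("full", n_persons=800, seed=7)
    bundle, truth = simulate_cohort(preset)
    return bundle, truth
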
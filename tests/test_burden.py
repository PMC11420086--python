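import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtri

from psycourse.burden import (
    NoOnsetError,
    group_burden_curve,
    int_transform,
    usage_profile,
    yearly_indicators,
)
from psycourse.registry import HospitalEpisode

from conftest import brute_force_burden, brute_force_usage

END = datetime.date(2018, 12, 31)
ONSET = datetime.date(2000, 3, 15)


def _episodes(spans):
    return [
        HospitalEpisode("p0", a, b, "F20.0") for a, b in spans
    ]


def _ep_frame(spans):
    return pd.DataFrame(
        {
            "person_id": "p0",
            "admit_date": [pd.Timestamp(a) for a, _ in spans],
            "discharge_date": [pd.Timestamp(b) for _, b in spans],
            "primary_code": "F20.0",
        }
    )


class TestYearlyIndicators:
    def test_no_episodes_zero_burden(self):
        s = yearly_indicators(_episodes([]), ONSET, END)
        assert s.burden_fraction == 0.0 and s.observed_years == 15

    def test_admission_every_year_full_burden(self):
        spans = [
            (ONSET + datetime.timedelta(days=int(k * 365.25) + 10),) * 2
            for k in range(15)
        ]
        s = yearly_indicators(_episodes([(a, b) for a, b in spans]), ONSET, END)
        assert s.burden_fraction == 1.0

    def test_three_marked_years_of_fifteen(self):
        spans = [
            (ONSET + datetime.timedelta(days=5), ONSET + datetime.timedelta(days=12)),
            (ONSET + datetime.timedelta(days=int(3 * 365.25) + 40),) * 2,
            (ONSET + datetime.timedelta(days=int(7 * 365.25) + 100), ONSET + datetime.timedelta(days=int(7 * 365.25) + 130)),
            (ONSET + datetime.timedelta(days=int(3 * 365.25) + 90),) * 2,  # same year twice
        ]
        marked, observed, fraction = brute_force_burden(spans, ONSET, END)
        s = yearly_indicators(_episodes(spans), ONSET, END)
        assert list(s.indicators) == marked
        assert s.burden_fraction == pytest.approx(fraction) == pytest.approx(3 / 15)

    def test_boundary_spanning_episode_marks_both_years(self):
        spans = [(ONSET + datetime.timedelta(days=360), ONSET + datetime.timedelta(days=370))]
        s = yearly_indicators(_episodes(spans), ONSET, END)
        assert s.indicators[0] and s.indicators[1] and sum(s.indicators) == 2

    def test_censoring_shrinks_denominator(self):
        onset = datetime.date(2014, 1, 1)
        s = yearly_indicators(_episodes([]), onset, END)
        assert s.observed_years == 5
        with pytest.raises(NoOnsetError):
            yearly_indicators(_episodes([]), None, END)
        with pytest.raises(ValueError):
            yearly_indicators(_episodes([]), datetime.date(2018, 12, 31), END)

    def test_burden_invariant_under_time_shift(self):
        spans = [
            (ONSET + datetime.timedelta(days=100), ONSET + datetime.timedelta(days=160)),
            (ONSET + datetime.timedelta(days=2000), ONSET + datetime.timedelta(days=2001)),
        ]
        base = yearly_indicators(_episodes(spans), ONSET, END)
        delta = datetime.timedelta(days=1234)
        shifted = yearly_indicators(
            _episodes([(a - delta, b - delta) for a, b in spans]), ONSET - delta, END
        )
        assert base.indicators == shifted.indicators
        assert base.burden_fraction == shifted.burden_fraction

    def test_extending_study_end_beyond_window_changes_nothing(self):
        spans = [(ONSET + datetime.timedelta(days=900), ONSET + datetime.timedelta(days=950))]
        a = yearly_indicators(_episodes(spans), ONSET, END)
        b = yearly_indicators(_episodes(spans), ONSET, datetime.date(2060, 1, 1))
        assert a == b


@given(
    st.lists(
        st.tuples(st.integers(-200, 6200), st.integers(0, 500)),
        max_size=6,
    ),
    st.integers(400, 9000),
)
def test_day_level_enumeration_oracle(spans_raw, follow_days):
    """Indicators, fraction, episode count, total and median LOS all agree
    with an independent per-day occupancy enumeration."""
    onset = datetime.date(1995, 6, 20)
    study_end = onset + datetime.timedelta(days=follow_days)
    spans = []
    for start, length in spans_raw:
        a = onset + datetime.timedelta(days=start)
        b = a + datetime.timedelta(days=length)
        if b <= study_end:
            spans.append((a, b))
    marked, observed, fraction = brute_force_burden(spans, onset, study_end)
    s = yearly_indicators(_ep_frame(spans) if spans else _episodes([]), onset, study_end)
    assert list(s.indicators) == marked
    assert s.observed_years == observed
    assert s.burden_fraction == pytest.approx(fraction)

    n, total, median = brute_force_usage(spans, onset)
    u = usage_profile(_ep_frame(spans) if spans else _episodes([]), onset)
    assert (u.n_episodes, u.total_los_days) == (n, total)
    assert u.median_los_days == median


class TestUsageProfile:
    def test_hand_arithmetic(self):
        spans = [
            (ONSET + datetime.timedelta(days=10), ONSET + datetime.timedelta(days=19)),    # 10 d
            (ONSET + datetime.timedelta(days=400), ONSET + datetime.timedelta(days=419)),  # 20 d
            (ONSET + datetime.timedelta(days=900), ONSET + datetime.timedelta(days=929)),  # 30 d
        ]
        u = usage_profile(_episodes(spans), ONSET)
        assert (u.n_episodes, u.total_los_days, u.median_los_days) == (3, 60, 20)

    def test_empty_and_single(self):
        u = usage_profile(_episodes([]), ONSET)
        assert (u.n_episodes, u.total_los_days, u.median_los_days) == (0, 0, None)
        one = usage_profile(
            _episodes([(ONSET, ONSET + datetime.timedelta(days=40))]), ONSET
        )
        assert one.median_los_days == 41

    def test_clipping_at_window_edge(self):
        far = ONSET + datetime.timedelta(days=5470)
        u = usage_profile(_episodes([(far, far + datetime.timedelta(days=100))]), ONSET)
        assert u.n_episodes == 1
        assert u.total_los_days == int(np.ceil(15 * 365.25)) - 5470


class TestIntTransform:
    def test_blom_scores_for_three_values(self):
        out = int_transform([1.0, 2.0, 3.0])
        expected = ndtri((np.array([1, 2, 3]) - 0.375) / 3.25)
        assert out == pytest.approx(expected)
        assert out[1] == 0.0 and out[2] == pytest.approx(-out[0])
        assert out[2] == pytest.approx(0.8694, abs=1e-3)

    def test_reversal_negates_and_ties_average(self):
        x = [3.0, 1.0, 4.0, 1.5]
        assert int_transform(x[::-1]) == pytest.approx(int_transform(x)[::-1])
        tied = int_transform([5.0, 5.0, 9.0, 9.0])
        assert tied[0] == tied[1] == pytest.approx(-tied[2])
        assert tied[2] == tied[3] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            int_transform([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            int_transform([1.0])


class TestGroupCurve:
    def _burden_table(self, rows):
        recs = []
        for pid, observed, years in rows:
            rec = {"person_id": pid, "observed_years": observed,
                   "burden_fraction": len(years) / observed}
            for k in range(15):
                rec[f"y{k}"] = int(k in years)
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_single_person_curve_equals_indicators(self):
        table = self._burden_table([("a", 15, {0, 2})])
        curve = group_burden_curve(table, pd.Series({"a": "g"}))
        props = curve.set_index("unit")["proportion"]
        assert props[0] == 1.0 and props[2] == 1.0 and props[1] == 0.0

    def test_hand_tallied_proportions(self):
        table = self._burden_table(
            [("a", 15, {0}), ("b", 15, {0, 1}), ("c", 2, {1}), ("d", 15, set()), ("e", 1, {0})]
        )
        groups = pd.Series({"a": "x", "b": "x", "c": "x", "d": "y", "e": "y"})
        curve = group_burden_curve(table, groups)
        x = curve[curve["group"] == "x"].set_index("unit")
        # year 0: a,b hospitalized of a,b,c observed; year 1: b,c of b,c... c observed y1 (2 observed years)
        assert x.loc[0, "proportion"] == pytest.approx(2 / 3)
        assert x.loc[1, "proportion"] == pytest.approx(2 / 3)
        assert x.loc[2, "n_observed"] == 2
        y = curve[curve["group"] == "y"].set_index("unit")
        assert y.loc[0, "proportion"] == pytest.approx(1 / 2)
        assert ((curve["proportion"] >= 0) & (curve["proportion"] <= 1)).all()
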
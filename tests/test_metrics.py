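import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gallop.config import AnalysisConfig, DEFAULT_CONFIG
from gallop.events import CareerTimeline, EventRecord, ValidationError, truncate_career
from gallop.metrics import (
    compute_variables,
    cumulative_curve,
    segment_layups,
    slope,
    windowed_distance,
)
from gallop.simulate import CareerParams, simulate_career

from conftest import day, make_horse

MONTH = DEFAULT_CONFIG.month_days


def timeline(specs, index_day):
    horse = make_horse("h", specs)
    return truncate_career(horse, day(index_day))


class TestLayupSegmentation:
    def test_gap_over_threshold_is_layup(self):
        tl = timeline(
            [(0, "work", 4.0), (30, "work", 4.0), (95, "work", 4.0), (100, "work", 4.0)],
            105,
        )
        seg = segment_layups(tl)
        assert seg.n_layups == 1
        assert seg.layups[0].duration_days == 65
        assert seg.career_length_days == 105
        assert seg.active_days == 40

    def test_sixty_day_gap_is_not_layup(self):
        tl = timeline([(0, "work", 4.0), (60, "work", 4.0)], 60)
        assert segment_layups(tl).n_layups == 0
        tl61 = timeline([(0, "work", 4.0), (61, "work", 4.0)], 61)
        assert segment_layups(tl61).n_layups == 1

    def test_trailing_gap_is_never_a_layup(self):
        tl = timeline([(0, "work", 4.0)], 200)
        seg = segment_layups(tl)
        assert seg.n_layups == 0 and seg.career_length_days == 200

    def test_single_event(self):
        seg = segment_layups(timeline([(0, "work", 4.0)], 10))
        assert (seg.n_layups, seg.career_length_days, seg.active_days) == (0, 10, 10)

    def test_empty_timeline_is_an_error(self):
        tl = CareerTimeline("h", day(0), ())
        with pytest.raises(ValidationError):
            segment_layups(tl)


class TestComputeVariables:
    def test_hand_countable_mixed_career(self, mixed_career):
        horse, tl = mixed_career
        v = compute_variables(tl, horse)
        assert v.n_events == 5 and v.n_races == 2 and v.n_works == 3
        assert v.event_dist_f == 24.0
        assert v.race_dist_f == 12.0 and v.work_dist_f == 12.0
        assert v.between_races_days == 30.0
        assert v.pct_career_in_layup == 0.0
        assert v.career_length_days == 60.0 and v.active_days == 60.0

    def test_rates_match_hand_computation(self, mixed_career):
        horse, tl = mixed_career
        v = compute_variables(tl, horse)
        assert v.races_per_year == pytest.approx(2 / (60 / 365.25))
        assert v.active_works_per_year == pytest.approx(3 / (60 / 365.25))
        assert v.career_event_rate_f_per_month == pytest.approx(24 / (60 / MONTH))
        assert v.dist_per_race_f == 6.0 and v.dist_per_work_f == 4.0

    def test_raceless_horse_has_missing_race_intervals(self):
        tl = timeline([(0, "work", 4.0), (14, "work", 4.0), (28, "work", 4.0)], 30)
        v = compute_variables(tl)
        assert v.races_per_year == 0.0
        assert v.between_races_days is None
        assert v.dist_per_race_f is None
        assert v.race_dist_f == 0.0

    def test_no_layup_horse_time_since_layup_spans_career(self):
        tl = timeline([(0, "work", 4.0), (20, "work", 4.0)], 30)
        v = compute_variables(tl)
        assert v.n_layups == 0 and v.mean_layup_time_days == 0.0
        assert v.time_since_last_layup_days == 30.0
        assert v.events_since_last_layup == v.n_events == 2

    def test_layup_variables(self):
        tl = timeline(
            [(0, "work", 4.0), (10, "work", 4.0), (110, "work", 4.0), (120, "work", 4.0)],
            125,
        )
        v = compute_variables(tl)
        assert v.n_layups == 1 and v.layup_time_days == 100.0
        assert v.mean_layup_time_days == 100.0
        assert v.pct_career_in_layup == pytest.approx(100 * 100 / 125)
        assert v.time_since_last_layup_days == 15.0  # from the layup-closing event
        assert v.events_since_last_layup == 2

    def test_active_gaps_subtract_layup_overlap(self):
        # races at 0 and 120 bridging a 100-day layup between works
        tl = timeline(
            [(0, "race", 6.0), (10, "work", 4.0), (110, "work", 4.0), (120, "race", 6.0)],
            125,
        )
        v = compute_variables(tl)
        assert v.between_races_days == 120.0
        assert v.between_races_active_days == 20.0

    def test_determinism_bitwise(self, mixed_career):
        horse, tl = mixed_career
        assert compute_variables(tl, horse) == compute_variables(tl, horse)


class TestWindowedDistance:
    def test_two_event_example(self):
        tl = timeline([(0, "race", 6.0), (35, "work", 4.0)], 45)
        # work is 10 days before index, race 45 days before
        assert windowed_distance(tl, 1, "before_index") == 4.0
        assert windowed_distance(tl, 2, "before_index") == 10.0

    def test_index_day_event_in_every_window(self):
        tl = timeline([(0, "work", 4.0), (45, "race", 6.0)], 45)
        for h in (1, 2, 4, 12):
            assert windowed_distance(tl, h, "before_index") >= 6.0

    def test_full_horizon_conserves_total(self, mixed_career):
        _, tl = mixed_career
        v = compute_variables(tl)
        assert windowed_distance(tl, 12, "before_index") == v.event_dist_f
        assert windowed_distance(tl, 12, "after_first_event") == v.event_dist_f

    def test_after_first_event_window_is_half_open(self):
        # event exactly at first + 1 month boundary is excluded
        boundary = int(MONTH)  # 30 days < 30.4375 -> included; use 31 to exclude
        tl = timeline([(0, "work", 4.0), (31, "work", 4.0)], 40)
        assert windowed_distance(tl, 1, "after_first_event") == 4.0


class TestCurveAndSlope:
    def test_step_values(self):
        tl = timeline([(0, "work", 4.0), (10, "race", 6.0)], 20)
        curve = cumulative_curve(tl)
        assert curve.value(day(0)) == 4.0
        assert curve.value(day(9)) == 4.0
        assert curve.value(day(10)) == 10.0
        assert curve.terminal == 10.0

    def test_same_day_events_merge_into_one_jump(self):
        tl = timeline([(0, "work", 4.0), (5, "work", 3.0), (5, "race", 6.0)], 10)
        curve = cumulative_curve(tl)
        assert curve.value(day(5)) == 13.0 and len(curve.dates) == 2

    def test_linear_accumulation_slope(self):
        # 4 F every 8 days: slope = 4 * (30.4375 / 8) f/month
        specs = [(8 * i, "work", 4.0) for i in range(8)]
        tl = timeline(specs, 60)
        curve = cumulative_curve(tl)
        s = slope(curve, (day(0), day(60)))
        assert s == pytest.approx(4 * MONTH / 8)

    def test_single_event_in_window_is_missing(self):
        tl = timeline([(0, "work", 4.0), (50, "work", 4.0)], 50)
        curve = cumulative_curve(tl)
        assert slope(curve, (day(40), day(60))) is None

    def test_doubling_distances_doubles_slope(self):
        specs = [(7 * i, "work", 4.0) for i in range(6)]
        tl1 = timeline(specs, 40)
        tl2 = timeline([(d, k, 2 * f) for d, k, f in specs], 40)
        s1 = slope(cumulative_curve(tl1), (day(0), day(40)))
        s2 = slope(cumulative_curve(tl2), (day(0), day(40)))
        assert s2 == pytest.approx(2 * s1)


career_strategy = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=500),
        st.sampled_from(["race", "work"]),
        st.floats(min_value=0.5, max_value=9.0, allow_nan=False),
    ),
    min_size=1,
    max_size=30,
)


class TestPanelProperties:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(career_strategy, st.integers(min_value=0, max_value=100))
    def test_conservation_counts_and_buckets(self, specs, extra):
        index_day = max(d for d, _, _ in specs) + extra
        tl = timeline(specs, index_day)
        v = compute_variables(tl)
        seg = segment_layups(tl)
        # layup/active conservation
        assert seg.active_days + seg.layup_time_days == seg.career_length_days
        # count and distance identities
        assert v.n_events == v.n_races + v.n_works
        assert v.event_dist_f == pytest.approx(v.race_dist_f + v.work_dist_f)
        if v.pct_career_in_layup is not None:
            assert 0.0 <= v.pct_career_in_layup <= 100.0
        # windowed monotonicity in horizon, both anchors
        before = [v.dist_before_1m_f, v.dist_before_2m_f, v.dist_before_4m_f,
                  v.dist_before_6m_f, v.dist_before_8m_f, v.dist_before_10m_f,
                  v.dist_before_12m_f]
        after = [v.dist_after_first_1m_f, v.dist_after_first_2m_f,
                 v.dist_after_first_4m_f, v.dist_after_first_6m_f,
                 v.dist_after_first_8m_f, v.dist_after_first_10m_f,
                 v.dist_after_first_12m_f]
        assert all(a <= b + 1e-12 for a, b in zip(before, before[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(after, after[1:]))
        # month-bucket identity chain
        assert v.dist_month2_f == pytest.approx(v.dist_before_2m_f - v.dist_before_1m_f)
        assert v.dist_months3_4_f == pytest.approx(v.dist_before_4m_f - v.dist_before_2m_f)
        assert v.dist_months5_6_f == pytest.approx(v.dist_before_6m_f - v.dist_before_4m_f)
        assert v.dist_month1_minus_month2_f == pytest.approx(
            v.dist_before_1m_f - v.dist_month2_f
        )

    def test_simulated_career_conservation(self):
        params = CareerParams()
        for i in range(25):
            horse = simulate_career(params, seed=1000 + i)
            tl = truncate_career(horse, horse.events[-1].date)
            seg = segment_layups(tl)
            assert seg.active_days + seg.layup_time_days == seg.career_length_days
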
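import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tie2response import (ProgressionRule, UnevaluableSeriesError,
                          combine_progression_calls, compare_detection_fractions,
                          detect_marker_progression, lead_time_detection)
from tie2response.progression import ProgressionCall
from .conftest import make_series


def call(patient_id, triggered, day, marker="TIE2"):
    return ProgressionCall(patient_id, marker, triggered, day, 10.0, 0)


class TestNadirRiseRule:
    def test_forty_percent_rise_triggers_at_boundary(self):
        s = make_series([0, 21, 42], [12.0, 10.0, 14.0])
        c = detect_marker_progression(s, ProgressionRule("TIE2", 0.40))
        assert c.triggered and c.trigger_day == 42
        assert c.nadir_value == 10.0 and c.nadir_day == 21

    def test_monotone_decreasing_never_triggers(self):
        s = make_series([0, 21, 42, 63], [12.0, 10.0, 9.0, 8.0])
        c = detect_marker_progression(s, ProgressionRule("TIE2", 0.40))
        assert not c.triggered and c.trigger_day is None
        assert c.nadir_value == 8.0

    def test_fifty_percent_rule_boundary(self):
        below = make_series([0, 21, 42], [11.0, 10.0, 14.9])
        at = make_series([0, 21, 42], [11.0, 10.0, 15.0])
        rule = ProgressionRule("CK18", 0.50)
        assert not detect_marker_progression(below, rule).triggered
        c = detect_marker_progression(at, rule)
        assert c.triggered and c.trigger_day == 42

    def test_nadir_excludes_current_measurement(self):
        # a single large jump must compare against earlier history only
        s = make_series([-7, 21], [10.0, 14.0])
        c = detect_marker_progression(s, ProgressionRule("TIE2", 0.40))
        assert c.triggered and c.trigger_day == 21  # 14 >= 1.4 * 10 (pre-treatment nadir)

    def test_confirmation_requires_consecutive_qualifying_visits(self):
        # one spike then return to nadir: no call under 2 confirmations
        spike = make_series([0, 21, 42, 63], [10.0, 15.0, 10.0, 10.0])
        rule2 = ProgressionRule("TIE2", 0.40, confirmations_required=2)
        assert not detect_marker_progression(spike, rule2).triggered
        sustained = make_series([0, 21, 42, 63], [10.0, 15.0, 15.0, 15.0])
        c = detect_marker_progression(sustained, rule2)
        assert c.triggered and c.trigger_day == 21  # first visit of the confirmed run

    def test_prior_vcr_gate(self):
        s = make_series([0, 21, 42], [12.0, 10.0, 14.0])
        rule = ProgressionRule("TIE2", 0.40, require_prior_vcr=True)
        assert not detect_marker_progression(s, rule, response_category="vPR").triggered
        assert detect_marker_progression(s, rule, response_category="vCR").triggered

    def test_single_measurement_unevaluable(self):
        with pytest.raises(UnevaluableSeriesError):
            detect_marker_progression(make_series([0], [10.0]), ProgressionRule("TIE2"))

    @given(
        st.lists(st.floats(1.0, 100.0), min_size=3, max_size=8),
        st.floats(0.05, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_trigger_day_nondecreasing_in_rise_fraction(self, conc, rise, bump):
        days = list(range(0, 21 * len(conc), 21))
        s = make_series(days, conc)
        loose = detect_marker_progression(s, ProgressionRule("TIE2", rise))
        strict = detect_marker_progression(s, ProgressionRule("TIE2", rise + bump))
        if strict.triggered:
            assert loose.triggered and loose.trigger_day <= strict.trigger_day


class TestCombine:
    def test_earliest_trigger_wins(self):
        combined = combine_progression_calls([call("P1", True, 100), call("P1", True, 80, "CK18")])
        assert combined.triggered and combined.trigger_day == 80
        assert combined.marker == "combined"

    def test_any_trigger_propagates(self):
        combined = combine_progression_calls([call("P1", False, None), call("P1", True, 60, "CK18")])
        assert combined.triggered and combined.trigger_day == 60

    def test_no_triggers_means_no_call(self):
        combined = combine_progression_calls([call("P1", False, None), call("P1", False, None, "CK18")])
        assert not combined.triggered and combined.trigger_day is None

    def test_empty_and_mixed_patient_inputs_rejected(self):
        with pytest.raises(UnevaluableSeriesError):
            combine_progression_calls([])
        with pytest.raises(ValueError):
            combine_progression_calls([call("P1", True, 10), call("P2", True, 20)])


class TestLeadTime:
    RAD = {"P1": 200.0, "P2": 200.0, "P3": 200.0}
    CALLS = {"combined": {"P1": call("P1", True, 150), "P2": call("P2", True, 170),
                          "P3": call("P3", False, None)}}

    def test_hand_counted_fraction_at_six_weeks(self):
        s = lead_time_detection(self.CALLS, self.RAD, 42)
        assert s.n_progressors == 3
        assert s.detected["combined"] == 1  # only day 150 <= 158
        assert s.fraction["combined"] == pytest.approx(1 / 3)

    def test_hand_counted_fraction_at_zero_lead(self):
        s = lead_time_detection(self.CALLS, self.RAD, 0)
        assert s.fraction["combined"] == pytest.approx(2 / 3)

    def test_fraction_nonincreasing_in_lead(self):
        fractions = [lead_time_detection(self.CALLS, self.RAD, L).fraction["combined"]
                     for L in (0, 21, 42, 63, 84)]
        assert all(b <= a for a, b in zip(fractions, fractions[1:]))

    def test_no_radiological_progressors_gives_empty_summary(self):
        s = lead_time_detection(self.CALLS, {"P1": None, "P2": float("nan")}, 42)
        assert s.n_progressors == 0 and np.isnan(s.fraction["combined"])

    def test_combined_dominates_singles_on_cohort(self, default_cohort):
        from tie2response.io import series_from_frame
        from tie2response.progression import DEFAULT_RISE
        series = series_from_frame(default_cohort.measurements)
        sets = {"vascular": {}, "epithelial": {}, "combined": {}}
        by_pid = {}
        for s in series:
            try:
                c = detect_marker_progression(s, ProgressionRule(s.marker, DEFAULT_RISE[s.marker]))
            except UnevaluableSeriesError:
                continue
            sets["vascular" if s.marker == "TIE2" else "epithelial"][s.patient_id] = c
            by_pid.setdefault(s.patient_id, []).append(c)
        for pid, calls in by_pid.items():
            sets["combined"][pid] = combine_progression_calls(calls)
        rad = dict(zip(default_cohort.patients.patient_id,
                       default_cohort.patients.rad_pd_day.astype(float)))
        for lead in (0, 42, 84):
            s = lead_time_detection(sets, rad, lead)
            assert s.fraction["combined"] >= max(s.fraction["vascular"], s.fraction["epithelial"])
            assert all(s.detected[k] <= s.n_progressors for k in s.detected)


class TestMcNemar:
    def test_ten_vs_zero_discordant(self):
        a = [True] * 10 + [False] * 5
        b = [False] * 10 + [False] * 5
        stat, p, degenerate = compare_detection_fractions(a, b)
        assert not degenerate
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_identical_indicators(self):
        stat, p, degenerate = compare_detection_fractions([True, False], [True, False])
        assert degenerate and p == 1.0

    def test_one_vs_one_discordant(self):
        a = [True, False, True]
        b = [False, True, True]
        _, p, degenerate = compare_detection_fractions(a, b)
        assert not degenerate and p == pytest.approx(1.0)
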
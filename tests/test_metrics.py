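"""Horizon-based evaluation metrics and chance baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import preictal as p
from preictal.io import GlobalSeizure
from preictal.metrics import evaluated_duration_s

H = 3600.0  # 60-minute horizon
HOUR = 3600.0


class TestNormalIntervals:
    def test_single_seizure_fig_layout(self):
        """6 h of coverage, seizure at hour 5 -> one normal interval [0, 4) h."""
        sz = [GlobalSeizure(5 * HOUR, 5 * HOUR + 30.0)]
        out = p.normal_intervals(sz, H, posthorizon_s=600.0,
                                 coverage=[(0.0, 6 * HOUR)])
        assert out == [(0.0, 4 * HOUR)]

    def test_no_seizures_whole_coverage_normal(self):
        out = p.normal_intervals([], H, 600.0, coverage=[(0.0, 6 * HOUR)])
        assert out == [(0.0, 6 * HOUR)]

    def test_overlapping_horizons_leave_no_interval(self):
        sz = [
            GlobalSeizure(2 * HOUR, 2 * HOUR + 30.0),
            GlobalSeizure(3 * HOUR, 3 * HOUR + 30.0),
        ]
        out = p.normal_intervals(sz, H, 600.0, coverage=[(0.0, 4 * HOUR)])
        # between the seizures: posthorizon ends 2h+30s+10min, next horizon
        # starts at 2h -> empty; only [0, 1h) before the first remains
        assert out == [(0.0, 1 * HOUR)]

    def test_clipped_to_coverage_pieces(self):
        sz = [GlobalSeizure(5 * HOUR, 5 * HOUR + 30.0)]
        coverage = [(0.0, 1 * HOUR), (2 * HOUR, 6 * HOUR)]
        out = p.normal_intervals(sz, H, 600.0, coverage=coverage)
        assert out == [(0.0, 1 * HOUR), (2 * HOUR, 4 * HOUR)]


class TestFalseWaitingTime:
    def test_two_disjoint_false_windows(self):
        fwt = p.false_waiting_time([1 * HOUR, 2.5 * HOUR], H,
                                   [(0.0, 4 * HOUR)])
        assert fwt == 2 * HOUR

    def test_no_false_alarms(self):
        assert p.false_waiting_time([], H, [(0.0, 4 * HOUR)]) == 0.0

    def test_window_clipped_at_interval_end(self):
        fwt = p.false_waiting_time([3.5 * HOUR], H, [(0.0, 4 * HOUR)])
        assert fwt == 0.5 * HOUR

    def test_overlapping_windows_count_once(self):
        fwt = p.false_waiting_time([HOUR, HOUR + 600.0], H, [(0.0, 4 * HOUR)])
        assert fwt == HOUR + 600.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        alarms=st.lists(
            st.integers(min_value=0, max_value=14000), max_size=12,
            unique=True,
        ),
        horizon=st.integers(min_value=100, max_value=4000),
    )
    def test_union_matches_one_second_grid(self, alarms, horizon):
        intervals = [(0.0, 5000.0), (8000.0, 15000.0)]
        fwt = p.false_waiting_time(sorted(map(float, alarms)), float(horizon),
                                   intervals)
        grid = np.zeros(16000, dtype=bool)
        for t in alarms:
            for s, e in intervals:
                if s <= t < e:
                    grid[int(t):int(min(t + horizon, e))] = True
        assert fwt == pytest.approx(grid.sum(), abs=1.0)


class TestSpecificitySensitivity:
    def test_specificity_values(self):
        assert p.specificity(2 * HOUR, 4 * HOUR) == 0.5
        assert p.specificity(0.0, 4 * HOUR) == 1.0
        assert p.specificity(4 * HOUR, 4 * HOUR) == 0.0
        assert np.isnan(p.specificity(0.0, 0.0))

    def test_sensitivity_ratio(self):
        sz = [GlobalSeizure(k * 4 * HOUR + 10 * HOUR, k * 4 * HOUR + 10 * HOUR + 30)
              for k in range(3)]
        alarms = [sz[0].onset - 600.0, sz[2].onset - 1800.0]
        series = p.classify_alarms(alarms, sz, H)
        assert p.sensitivity(series, sz, H) == pytest.approx(2 / 3)

    def test_no_alarms_zero_sensitivity(self):
        sz = [GlobalSeizure(10 * HOUR, 10 * HOUR + 30)]
        series = p.classify_alarms([], sz, H)
        assert p.sensitivity(series, sz, H) == 0.0

    def test_no_evaluable_seizures_not_applicable(self):
        series = p.classify_alarms([], [], H)
        assert np.isnan(p.sensitivity(series, [], H))


class TestFprAndPredictionTime:
    def test_fpr_uses_merged_count(self):
        series = p.classify_alarms([1000.0, 1600.0], [], H)  # merge to one
        n_false = series.count("false", merged_as_one=True)
        assert p.fpr(n_false, 4.0) == 0.25

    def test_fpr_zero_duration_not_applicable(self):
        assert np.isnan(p.fpr(3, 0.0))

    def test_earliest_positive_alarm_defines_prediction_time(self):
        sz = [GlobalSeizure(10 * HOUR, 10 * HOUR + 30)]
        alarms = [sz[0].onset - 1800.0, sz[0].onset - 600.0]
        series = p.classify_alarms(alarms, sz, H)
        times, mean = p.prediction_time(series, sz, H)
        assert times == [30.0]
        assert mean == 30.0

    def test_alarm_ten_minutes_before_onset(self):
        sz = [GlobalSeizure(10 * HOUR, 10 * HOUR + 30)]
        series = p.classify_alarms([sz[0].onset - 600.0], sz, H)
        times, mean = p.prediction_time(series, sz, H)
        assert times == [10.0]

    def test_no_predictions_mean_not_applicable(self):
        sz = [GlobalSeizure(10 * HOUR, 10 * HOUR + 30)]
        series = p.classify_alarms([], sz, H)
        times, mean = p.prediction_time(series, sz, H)
        assert times == [] and np.isnan(mean)


class TestBaselines:
    def test_periodic_two_hour_period(self):
        spec = p.BaselineSpec(kind="periodic", period_or_mean_h=2.0)
        out = p.baseline_alarms(spec, [(0.0, 6 * HOUR)])
        assert out == [2 * HOUR, 4 * HOUR, 6 * HOUR]

    def test_periodic_skips_gaps(self):
        spec = p.BaselineSpec(kind="periodic", period_or_mean_h=2.0)
        out = p.baseline_alarms(spec, [(0.0, 3 * HOUR), (5 * HOUR, 8 * HOUR)])
        assert out == [2 * HOUR, 6 * HOUR, 8 * HOUR]

    def test_poisson_seeded_determinism(self):
        spec = p.BaselineSpec(kind="poisson", period_or_mean_h=1.0, seed=4)
        a = p.baseline_alarms(spec, [(0.0, 100 * HOUR)])
        b = p.baseline_alarms(spec, [(0.0, 100 * HOUR)])
        assert a == b and len(a) > 0

    def test_poisson_mean_interval_converges(self):
        spec = p.BaselineSpec(kind="poisson", period_or_mean_h=1.0, seed=7)
        out = np.array(p.baseline_alarms(spec, [(0.0, 1000 * HOUR)]))
        intervals = np.diff(np.concatenate([[0.0], out])) / HOUR
        se = 1.0 / np.sqrt(len(intervals))
        assert abs(intervals.mean() - 1.0) < 3 * se


class TestWorkedExample:
    def build(self):
        """6 h coverage, seizure at hour 5, alarms at 1 h, 2.5 h, 4.5 h."""
        sz = [GlobalSeizure(5 * HOUR, 5 * HOUR + 30.0)]
        alarms = [1 * HOUR, 2.5 * HOUR, 4.5 * HOUR]
        return p.evaluate(alarms, sz, H, coverage=[(0.0, 6 * HOUR)])

    def test_reference_timeline_metrics(self):
        result = self.build()
        assert result.sensitivity == 1.0
        assert result.fwt_s == 2 * HOUR
        assert result.np_s == 4 * HOUR
        assert result.specificity == 0.5

    def test_conservation_identity(self):
        result = self.build()
        assert result.specificity + result.fwt_s / result.np_s == 1.0


class TestMonotonicity:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        alarms=st.lists(
            st.floats(min_value=0, max_value=6 * HOUR - 1), max_size=8,
            unique=True,
        ),
        extra=st.floats(min_value=0, max_value=4 * HOUR - 1),
    )
    def test_added_false_alarm_never_raises_specificity(self, alarms, extra):
        sz = [GlobalSeizure(5 * HOUR, 5 * HOUR + 30.0)]
        base = p.evaluate(sorted(alarms), sz, H, coverage=[(0.0, 6 * HOUR)])
        more = p.evaluate(sorted(set(alarms) | {extra}), sz, H,
                          coverage=[(0.0, 6 * HOUR)])
        assert more.specificity <= base.specificity + 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        alarms=st.lists(
            st.floats(min_value=0, max_value=6 * HOUR - 1), max_size=8,
            unique=True,
        ),
        offset=st.floats(min_value=1.0, max_value=H - 1),
    )
    def test_added_positive_alarm_never_lowers_sensitivity(self, alarms,
                                                           offset):
        sz = [GlobalSeizure(5 * HOUR, 5 * HOUR + 30.0)]
        base = p.evaluate(sorted(alarms), sz, H, coverage=[(0.0, 6 * HOUR)])
        more = p.evaluate(sorted(set(alarms) | {sz[0].onset - offset}), sz, H,
                          coverage=[(0.0, 6 * HOUR)])
        assert more.sensitivity >= base.sensitivity


def test_evaluated_duration_excludes_seizure_and_margins():
    sz = [GlobalSeizure(2 * HOUR, 2 * HOUR + 60.0)]
    dur = evaluated_duration_s(
        [(0.0, 6 * HOUR)], sz, postictal_s=600.0,
        gaps=[(6 * HOUR, 7 * HOUR)], gap_margin_s=600.0,
    )
    assert dur == 6 * HOUR - (600.0 + 60.0) - 600.0
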
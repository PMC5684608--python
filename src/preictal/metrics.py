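"""Horizon-based evaluation: sensitivity, false-waiting-time specificity,
false prediction rate, prediction time, and chance-level baselines.

The specificity follows the false-waiting-time formulation
``spec = 1 − fwt / np``: ``np`` is the total length of the *normal
intervals* — stretches from the end of one seizure's posthorizon to the
start of the next seizure's prediction horizon — and ``fwt`` is the union
length of the waiting windows opened by false alarms (alarm time to the end
of its horizon, clipped to the surrounding normal interval). Using the union
rather than the sum keeps overlapping false horizons "counted as one" and
guarantees ``spec`` ∈ [0, 1].

Worked reference case: 6 h of continuous coverage, one seizure at hour 5,
60-min horizon, false alarms at hours 1 and 2.5 and one alarm inside the
horizon. The single normal interval is [0 h, 4 h), the two false windows
cover 2 h, hence sensitivity 100% and specificity 1 − 2/4 = 50%.

Boundary conventions: coverage start acts as a posthorizon end (the first
normal interval starts there), and after the *last* seizure no normal
interval is emitted, since no following seizure defines its end; with zero
seizures the whole coverage is one normal interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alarms import FALSE, POSITIVE, AlarmSeries, classify_alarms
from .io import GlobalSeizure

log = logging.getLogger("preictal")

Interval = tuple[float, float]


# ---------------------------------------------------------------------------
# Interval arithmetic (half-open [start, end))
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return _merge_intervals(out)


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    result = list(_merge_intervals(a))
    for s2, e2 in _merge_intervals(b):
        nxt = []
        for s1, e1 in result:
            if e2 <= s1 or s2 >= e1:
                nxt.append((s1, e1))
                continue
            if s1 < s2:
                nxt.append((s1, s2))
            if e2 < e1:
                nxt.append((e2, e1))
        result = nxt
    return result


def _total_length(intervals: Sequence[Interval]) -> float:
    return sum(e - s for s, e in _merge_intervals(intervals))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineSpec:
    """A chance-level predictor: periodic (period T) or Poisson (mean M)."""

    kind: str  # "periodic" | "poisson"
    period_or_mean_h: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("periodic", "poisson"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.period_or_mean_h <= 0:
            raise ValueError("baseline period/mean must be positive")


@dataclass
class EvaluationResult:
    """Metrics for one predictor on one record set (NaN = not applicable)."""

    sensitivity: float
    specificity: float
    fpr_per_h: float
    mean_prediction_time_min: float
    prediction_times_min: list[float] = field(default_factory=list)
    fwt_s: float = 0.0
    np_s: float = 0.0
    n_seizures: int = 0
    n_predicted: int = 0
    n_false_alarms: int = 0
    evaluated_hours: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fpr_per_h": self.fpr_per_h,
            "mean_prediction_time_min": self.mean_prediction_time_min,
            "fwt_s": self.fwt_s,
            "np_s": self.np_s,
            "n_seizures": self.n_seizures,
            "n_predicted": self.n_predicted,
            "n_false_alarms": self.n_false_alarms,
            "evaluated_hours": self.evaluated_hours,
        }


# ---------------------------------------------------------------------------
# Normal intervals and false waiting time
# ---------------------------------------------------------------------------

def normal_intervals(seizures: Sequence[GlobalSeizure],
                     horizon_s: float,
                     posthorizon_s: float,
                     coverage: Sequence[Interval]) -> list[Interval]:
    """Normal (alarm-penalized) intervals between seizures, clipped to coverage.

    Each interval runs from the end of the previous seizure's posthorizon
    (or coverage start, for the first) to the start of the next seizure's
    prediction horizon. No interval is emitted after the last seizure; with
    no seizures the whole coverage is normal.
    """
    cov = _merge_intervals(coverage)
    if not cov:
        return []
    if not seizures:
        return cov
    seizures = sorted(seizures, key=lambda s: s.onset)
    lo = cov[0][0]
    raw: list[Interval] = []
    prev_end = lo
    for sz in seizures:
        raw.append((prev_end, sz.onset - horizon_s))
        prev_end = sz.offset + posthorizon_s
    return _intersect(raw, cov)


def false_waiting_time(false_alarms: Sequence[float],
                       horizon_s: float,
                       intervals: Sequence[Interval]) -> float:
    """Union length of false-alarm waiting windows, clipped to their interval.

    Each false alarm opens a window from the alarm to the end of its
    horizon or the end of the normal interval containing it, whichever
    comes first; overlapping windows count once.
    """
    windows = []
    for t in false_alarms:
        for s, e in intervals:
            if s <= t < e:
                windows.append((t, min(t + horizon_s, e)))
                break
    return _total_length(windows)


def specificity(fwt_s: float, np_s: float) -> float:
    """``1 − fwt/np``; NaN when no normal time exists (not applicable)."""
    if np_s <= 0:
        return float("nan")
    return 1.0 - fwt_s / np_s


def sensitivity(alarm_series: AlarmSeries,
                seizures: Sequence[GlobalSeizure],
                horizon_s: float) -> float:
    """Fraction of evaluable seizures with >= 1 positive alarm in their horizon."""
    evaluable = [sz for sz in seizures if not sz.excluded]
    if not evaluable:
        return float("nan")
    pos = alarm_series.times(POSITIVE)
    n_pred = sum(
        any(sz.onset - horizon_s <= t < sz.onset for t in pos)
        for sz in evaluable
    )
    return n_pred / len(evaluable)


def fpr(n_false_merged: int, evaluated_hours: float) -> float:
    """Merged false alarms per evaluated hour; NaN for zero duration."""
    if evaluated_hours <= 0:
        return float("nan")
    return n_false_merged / evaluated_hours


def prediction_time(alarm_series: AlarmSeries,
                    seizures: Sequence[GlobalSeizure],
                    horizon_s: float) -> tuple[list[float], float]:
    """Minutes from the earliest positive alarm to onset, per predicted seizure."""
    pos = alarm_series.times(POSITIVE)
    times = []
    for sz in seizures:
        if sz.excluded:
            continue
        in_horizon = [t for t in pos if sz.onset - horizon_s <= t < sz.onset]
        if in_horizon:
            times.append((sz.onset - min(in_horizon)) / 60.0)
    mean = float(np.mean(times)) if times else float("nan")
    return times, mean


def evaluated_duration_s(coverage: Sequence[Interval],
                         seizures: Sequence[GlobalSeizure],
                         postictal_s: float = 600.0,
                         gaps: Sequence[Interval] = (),
                         gap_margin_s: float = 600.0) -> float:
    """Coverage minus ictal + postictal time and gap margins (FPR denominator)."""
    excl = [(sz.onset, sz.offset + postictal_s) for sz in seizures]
    excl += [(gs - gap_margin_s, ge + gap_margin_s) for gs, ge in gaps]
    return _total_length(_subtract(coverage, excl))


def baseline_alarms(spec: BaselineSpec,
                    coverage: Sequence[Interval]) -> list[float]:
    """Alarm times for a chance predictor over the given coverage.

    Periodic: alarms every T hours from coverage start; Poisson: cumulative
    exponential inter-alarm intervals with mean M hours (seeded). Alarms
    falling in gaps between coverage pieces are dropped.
    """
    cov = _merge_intervals(coverage)
    if not cov:
        return []
    t0, t1 = cov[0][0], cov[-1][1]
    period_s = spec.period_or_mean_h * 3600.0
    if spec.kind == "periodic":
        times = np.arange(t0 + period_s, t1 + 1e-9, period_s)
    else:
        rng = np.random.default_rng(spec.seed)
        times = []
        t = t0
        while True:
            t += rng.exponential(period_s)
            if t > t1:
                break
            times.append(t)
        times = np.asarray(times)
    return [float(t) for t in times if any(s <= t <= e for s, e in cov)]


# ---------------------------------------------------------------------------
# One-call evaluation
# ---------------------------------------------------------------------------

def evaluate(alarm_times: Sequence[float],
             seizures: Sequence[GlobalSeizure],
             horizon_s: float,
             coverage: Sequence[Interval],
             postictal_s: float = 600.0,
             posthorizon_s: float | None = None,
             gaps: Sequence[Interval] = (),
             gap_margin_s: float = 600.0) -> EvaluationResult:
    """Classify raw alarm times against the timeline and compute all metrics.

    ``posthorizon_s`` (the dead time after a seizure before normal time
    resumes) defaults to ``postictal_s``. Seizures outside ``coverage`` are
    still used for classification but only those with onset inside coverage
    enter the sensitivity denominator.
    """
    if posthorizon_s is None:
        posthorizon_s = postictal_s
    series = classify_alarms(alarm_times, seizures, horizon_s, gaps=gaps,
                             postictal_s=postictal_s,
                             gap_margin_s=gap_margin_s)
    cov = _merge_intervals(coverage)
    in_cov = [
        sz for sz in seizures
        if any(s <= sz.onset < e for s, e in cov)
    ]
    evaluable = [sz for sz in in_cov if not sz.excluded]
    intervals = normal_intervals(seizures, horizon_s, posthorizon_s, cov)
    np_s = _total_length(intervals)
    fwt_s = false_waiting_time(series.times(FALSE), horizon_s, intervals)
    times_min, mean_time = prediction_time(series, evaluable, horizon_s)
    n_false = series.count(FALSE, merged_as_one=True)
    hours = evaluated_duration_s(cov, seizures, postictal_s, gaps,
                                 gap_margin_s) / 3600.0
    pos = series.times(POSITIVE)
    n_pred = sum(
        any(sz.onset - horizon_s <= t < sz.onset for t in pos)
        for sz in evaluable
    )
    sens = n_pred / len(evaluable) if evaluable else float("nan")
    return EvaluationResult(
        sensitivity=sens,
        specificity=specificity(fwt_s, np_s),
        fpr_per_h=fpr(n_false, hours),
        mean_prediction_time_min=mean_time,
        prediction_times_min=times_min,
        fwt_s=fwt_s,
        np_s=np_s,
        n_seizures=len(evaluable),
        n_predicted=n_pred,
        n_false_alarms=n_false,
        evaluated_hours=hours,
    )
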
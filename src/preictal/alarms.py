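"""Run-length alarm generation, alarm classification, and α selection.

The smoothed classifier output is scanned for runs of consecutive preictal
decisions: an alarm fires the instant a run first reaches the
patient-specific threshold α (seconds of sustained detection), with at most
one alarm per maximal run (the run must break before the detector can fire
again). Each alarm is then classified against the seizure timeline:

* **positive** — inside ``[onset − horizon, onset)`` of a non-excluded
  seizure;
* **discarded** — inside ictal/postictal time, within the 10-min margin of a
  recording gap, or in the horizon of an *excluded* seizure (which is
  outside the evaluation denominator either way);
* **false** — everything else.

Consecutive same-type alarms falling inside the horizon window opened by an
earlier alarm are merged into it (counted once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io import GlobalSeizure
from .lda import BinarySeries

log = logging.getLogger("preictal")

POSITIVE = "positive"
FALSE = "false"
DISCARDED = "discarded"

#: Default grid of run-length thresholds (seconds) searched during training.
DEFAULT_ALPHA_GRID = (3, 5, 10, 20, 40, 60, 90, 120)


@dataclass(frozen=True)
class AlarmConfig:
    alpha: int
    horizon_s: float = 3600.0
    gap_margin_s: float = 600.0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")


@dataclass(frozen=True)
class ClassifiedAlarm:
    time: float
    type: str  # positive | false | discarded
    merged: bool = False  # absorbed into an earlier same-type alarm's horizon


@dataclass
class AlarmSeries:
    """Classified alarms for one evaluation, in increasing time order."""

    alarms: list[ClassifiedAlarm]
    horizon_s: float

    def __post_init__(self) -> None:
        times = [a.time for a in self.alarms]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("alarm times must be strictly increasing")

    def times(self, type: str | None = None,
              include_merged: bool = True) -> list[float]:
        return [
            a.time for a in self.alarms
            if (type is None or a.type == type)
            and (include_merged or not a.merged)
        ]

    def count(self, type: str, merged_as_one: bool = True) -> int:
        return len(self.times(type, include_merged=not merged_as_one))


def raise_alarms(series: BinarySeries, alpha: int) -> list[float]:
    """Emit one alarm per maximal 1-run reaching length ``alpha``.

    The alarm time is the global time of the α-th consecutive preictal
    second (first crossing); the run must break to zero before another
    alarm can fire.
    """
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")
    out = []
    run = 0
    for i, v in enumerate(series.values):
        if v:
            run += 1
            if run == alpha:
                out.append(series.time_of(i))
        else:
            run = 0
    return out


def classify_alarms(alarms: Sequence[float],
                    seizures: Sequence[GlobalSeizure],
                    horizon_s: float,
                    gaps: Sequence[tuple[float, float]] = (),
                    postictal_s: float = 600.0,
                    gap_margin_s: float = 600.0) -> AlarmSeries:
    """Assign each alarm exactly one type and merge within-horizon repeats."""
    seizures = sorted(seizures, key=lambda s: s.onset)
    margin_zones = [
        (gs - gap_margin_s, ge + gap_margin_s) for gs, ge in gaps
    ]
    classified: list[ClassifiedAlarm] = []
    last_kept: dict[str, float] = {}
    for t in sorted(alarms):
        if any(s <= t < e for s, e in margin_zones):
            kind = DISCARDED
        elif any(sz.onset <= t < sz.offset + postictal_s for sz in seizures):
            kind = DISCARDED
        elif any(
            sz.onset - horizon_s <= t < sz.onset and not sz.excluded
            for sz in seizures
        ):
            kind = POSITIVE
        elif any(
            sz.onset - horizon_s <= t < sz.onset and sz.excluded
            for sz in seizures
        ):
            kind = DISCARDED
        else:
            kind = FALSE
        merged = (
            kind in last_kept and t < last_kept[kind] + horizon_s
        )
        if not merged:
            last_kept[kind] = t
        classified.append(ClassifiedAlarm(time=t, type=kind, merged=merged))
    return AlarmSeries(alarms=classified, horizon_s=horizon_s)


def select_alpha(training_runs: Sequence[tuple[BinarySeries,
                                               Sequence[GlobalSeizure]]],
                 horizon_s: float,
                 alpha_grid: Sequence[int] = DEFAULT_ALPHA_GRID,
                 gaps: Sequence[tuple[float, float]] = (),
                 postictal_s: float = 600.0) -> int:
    """Pick the run-length threshold from training alarm performance.

    For each grid value, alarms are raised on every training series and
    pooled: the α maximizing sensitivity wins, ties broken by lowest false
    alarm rate (merged false alarms per series hour), then by the largest
    α (the most conservative detector). Deterministic.
    """
    if not alpha_grid:
        raise ValueError("alpha grid must be non-empty")
    best: tuple[float, float, int] | None = None
    best_alpha = None
    for alpha in alpha_grid:
        predicted = evaluable = 0
        false_count = 0
        hours = 0.0
        for series, seizures in training_runs:
            end = series.start_time + len(series) * series.step_s
            result = classify_alarms(
                raise_alarms(series, alpha), seizures, horizon_s,
                gaps=gaps, postictal_s=postictal_s,
            )
            pos = result.times(POSITIVE)
            for sz in seizures:
                if sz.excluded or not series.start_time < sz.onset <= end:
                    continue
                evaluable += 1
                if any(sz.onset - horizon_s <= t < sz.onset for t in pos):
                    predicted += 1
            false_count += result.count(FALSE, merged_as_one=True)
            hours += len(series) * series.step_s / 3600.0
        sens = predicted / evaluable if evaluable else 0.0
        fa_rate = false_count / hours if hours > 0 else 0.0
        key = (sens, -fa_rate, alpha)
        if best is None or key > best:
            best, best_alpha = key, alpha
    if best is not None and best[0] == 0.0:
        log.warning(
            "no alpha in the grid predicted any training seizure; "
            "falling back to the most conservative value %d", best_alpha,
        )
    return int(best_alpha)
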
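"""Sliding-window epoch extraction and preictal/interictal labelling.

Recordings are framed into overlapping epochs (default 3 s window, 1 s
step, i.e. an overlap of window − 1 seconds). Each epoch is then labelled:

* **preictal** — lies entirely inside the preictal training window
  ``[onset − offset − len, onset − offset)`` of a non-excluded seizure
  (offset 0 ends the window right at seizure onset; offsets of 60/120 min
  shift it earlier);
* **excluded** — overlaps ictal time, the 10-min postictal interval, the
  10-min margin around a recording gap, or the buffer between a shifted
  preictal window and onset;
* **interictal** — everything else. For *training*, interictal epochs are
  additionally restricted to seizure-free records (handled by the pipeline);
  for testing all interictal epochs count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GlobalSeizure, Recording

log = logging.getLogger("preictal")

PREICTAL = "preictal"
INTERICTAL = "interictal"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing and labelling parameters (seconds).

    Defaults follow the predictor's operating point: 3 s epochs stepped by
    1 s, a 3-min preictal window ending at onset, 10-min postictal and
    gap-margin exclusions.
    """

    window_s: float = 3.0
    step_s: float = 1.0
    preictal_len_s: float = 180.0
    preictal_offset_s: float = 0.0
    postictal_s: float = 600.0
    gap_margin_s: float = 600.0

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("need 0 < step_s <= window_s")
        if self.preictal_len_s <= 0:
            raise ValueError("preictal_len_s must be positive")


@dataclass(eq=False)
class Epoch:
    """One windowed segment: ``data`` is a channels x samples view."""

    data: np.ndarray
    start_time: float  # global seconds
    record_id: str

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochLabeling:
    """Per-epoch class labels with exclusion reasons."""

    labels: np.ndarray  # of {preictal, interictal, excluded}
    reasons: np.ndarray  # of {ictal, postictal, gap_margin, horizon_buffer, none}

    def __post_init__(self) -> None:
        if self.labels.shape != self.reasons.shape:
            raise ValueError("labels and reasons must align")

    def counts(self) -> dict[str, int]:
        uniq, n = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), n.tolist()))


def n_epochs(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of full windows: floor((duration − window)/step) + 1 (0 if short)."""
    if duration_s < window_s:
        return 0
    # tiny tolerance so durations that are exact multiples are not lost to
    # floating-point representation
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def sliding_epochs(recording: Recording,
                   config: SegmentationConfig) -> list[Epoch]:
    """Frame a recording into overlapping epochs.

    Epoch k starts at ``recording.start_time + k * step_s``; no partial
    trailing epoch is emitted. Data arrays are views into the recording.
    """
    count = n_epochs(recording.duration_s, config.window_s, config.step_s)
    if count == 0:
        log.warning(
            "recording %r (%.1f s) shorter than the %.1f s window: no epochs",
            recording.record_id, recording.duration_s, config.window_s,
        )
        return []
    win = int(round(config.window_s * recording.fs))
    step = config.step_s * recording.fs
    epochs = []
    for k in range(count):
        i0 = int(round(k * step))
        epochs.append(
            Epoch(
                data=recording.signal[:, i0:i0 + win],
                start_time=recording.start_time + k * config.step_s,
                record_id=recording.record_id,
            )
        )
    return epochs


def _overlaps(t0: float, t1: float, s: float, e: float) -> bool:
    return t0 < e and s < t1


def preictal_window(seizure_onset: float,
                    config: SegmentationConfig) -> tuple[float, float]:
    """Global interval supplying preictal epochs for one seizure."""
    end = seizure_onset - config.preictal_offset_s
    return end - config.preictal_len_s, end


def label_epochs(epochs: Sequence[Epoch],
                 seizures: Sequence[GlobalSeizure],
                 config: SegmentationConfig,
                 gaps: Sequence[tuple[float, float]] = (),
                 coverage: Sequence[tuple[float, float]] | None = None,
                 ) -> EpochLabeling:
    """Label epochs against policy-applied seizures on the global clock.

    Exclusion precedence: ictal > postictal > gap_margin > horizon_buffer.
    ``horizon_buffer`` marks the stretch between a shifted preictal window
    and seizure onset (only when ``preictal_offset_s > 0``) so shifted-window
    training never sees late-preictal data it claims to avoid.
    """
    n = len(epochs)
    labels = np.full(n, INTERICTAL, dtype=object)
    reasons = np.full(n, "none", dtype=object)

    pre_windows = [
        preictal_window(sz.onset, config) for sz in seizures if not sz.excluded
    ]
    buffer_windows = (
        [(sz.onset - config.preictal_offset_s, sz.onset)
         for sz in seizures if not sz.excluded]
        if config.preictal_offset_s > 0 else []
    )
    margin_zones = [
        (gs - config.gap_margin_s, ge + config.gap_margin_s) for gs, ge in gaps
    ]

    n_clipped = 0
    for i, ep in enumerate(epochs):
        t0 = ep.start_time
        t1 = t0 + config.window_s
        if any(_overlaps(t0, t1, sz.onset, sz.offset) for sz in seizures):
            labels[i], reasons[i] = EXCLUDED, "ictal"
        elif any(
            _overlaps(t0, t1, sz.offset, sz.offset + config.postictal_s)
            for sz in seizures
        ):
            labels[i], reasons[i] = EXCLUDED, "postictal"
        elif any(_overlaps(t0, t1, s, e) for s, e in margin_zones):
            labels[i], reasons[i] = EXCLUDED, "gap_margin"
        elif any(s <= t0 and t1 <= e for s, e in pre_windows):
            labels[i] = PREICTAL
        elif any(_overlaps(t0, t1, s, e) for s, e in buffer_windows):
            labels[i], reasons[i] = EXCLUDED, "horizon_buffer"

    if coverage is not None:
        # count preictal-window seconds that extend before recorded coverage
        for s, e in pre_windows:
            from .io import _overlap_length
            missing = (e - s) - _overlap_length((s, e), coverage)
            if missing > 1e-9:
                n_clipped += 1
                log.info(
                    "preictal window [%.1f, %.1f) misses %.1f s of coverage; "
                    "uncovered epochs dropped", s, e, missing,
                )
    if n_clipped:
        log.info("%d preictal windows clipped by coverage", n_clipped)
    return EpochLabeling(labels=labels, reasons=reasons)
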
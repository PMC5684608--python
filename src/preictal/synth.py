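"""Synthetic multichannel EEG with state-dependent spatial covariance.

The generator emulates exactly what the CSP + log-variance predictor reads
from scalp EEG: a zero-mean multichannel Gaussian signal whose *spatial
covariance* differs between the interictal and preictal states, organised as
a timeline of seizures with configurable preictal structure and optional
recording gaps ("missing hours"). It deliberately models nothing else — no
1/f spectrum, rhythms or artifacts — because second-order spatial structure
is the only property the method consumes.

The two state covariances share an eigenbasis; their eigenvalues are pulled
apart by a single ``separation`` knob so the generalized eigenvalue spectrum
(the quantity CSP estimates) is known in closed form:
``lambda_i = 1 / (1 + exp(-separation * s_i))`` with ``s_i`` spread over
[-1, 1]. ``separation = 0`` makes the states identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Recording, RecordSet, SeizureAnnotation

log = logging.getLogger("preictal")

#: Variance multiplier applied to the preictal covariance during ictal
#: samples. Ictal content is excluded from training and evaluation; it only
#: needs to exist on the timeline.
ICTAL_BURST_FACTOR = 5.0


@dataclass
class StateCovarianceSpec:
    """A matched pair of interictal / preictal spatial covariances."""

    n_channels: int
    interictal_cov: np.ndarray
    preictal_cov: np.ndarray
    separation: float

    def __post_init__(self) -> None:
        for name in ("interictal_cov", "preictal_cov"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError(f"{name} must be {self.n_channels}x{self.n_channels}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
            setattr(self, name, m)


@dataclass
class TimelineSpec:
    """Layout of one synthetic patient timeline.

    All times in global seconds. Gaps are intervals removed from recording
    coverage; seizures and gaps must lie within ``duration_s`` and seizures
    must not overlap each other.
    """

    duration_s: float
    seizure_onsets_s: list[float] = field(default_factory=list)
    seizure_durations_s: list[float] = field(default_factory=list)
    preictal_len_s: float = 180.0
    gap_intervals: list[tuple[float, float]] = field(default_factory=list)
    fs: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.seizure_onsets_s) != len(self.seizure_durations_s):
            raise ValueError("one duration per seizure onset required")
        order = np.argsort(self.seizure_onsets_s)
        self.seizure_onsets_s = [self.seizure_onsets_s[i] for i in order]
        self.seizure_durations_s = [self.seizure_durations_s[i] for i in order]
        prev_end = -np.inf
        for on, dur in zip(self.seizure_onsets_s, self.seizure_durations_s):
            if dur <= 0:
                raise ValueError("seizure durations must be positive")
            if on < prev_end:
                raise ValueError("seizures must not overlap")
            if on + dur > self.duration_s:
                raise ValueError("seizure extends past timeline end")
            prev_end = on + dur
        for s, e in self.gap_intervals:
            if not 0 <= s < e <= self.duration_s:
                raise ValueError(f"gap ({s}, {e}) outside timeline")

    def seizure_intervals(self) -> list[tuple[float, float]]:
        return [
            (on, on + dur)
            for on, dur in zip(self.seizure_onsets_s, self.seizure_durations_s)
        ]


def make_state_covariances(n_channels: int, separation: float,
                           seed: int) -> StateCovarianceSpec:
    """Construct a random SPD covariance pair with controlled separability.

    Both matrices share a random orthogonal eigenbasis and log-spaced base
    eigenvalues (one decade); the preictal eigenvalues are scaled by
    ``exp(separation * s_i)`` with ``s_i`` linearly spread over [1, -1], so
    the generalized eigenvalues of ``(preictal, preictal + interictal)``
    spread monotonically around 0.5 as ``separation`` grows. At
    ``separation = 0`` the two matrices are identical.
    """
    if n_channels < 2:
        raise ValueError(f"n_channels must be >= 2, got {n_channels}")
    if separation < 0:
        raise ValueError(f"separation must be >= 0, got {separation}")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    base = np.logspace(0.0, -1.0, n_channels)
    spread = np.linspace(1.0, -1.0, n_channels)
    interictal = q @ np.diag(base) @ q.T
    interictal = (interictal + interictal.T) / 2
    if separation == 0:
        preictal = interictal.copy()
    else:
        pre_eigs = base * np.exp(separation * spread)
        preictal = q @ np.diag(pre_eigs) @ q.T
        preictal = (preictal + preictal.T) / 2
    return StateCovarianceSpec(
        n_channels=n_channels,
        interictal_cov=interictal,
        preictal_cov=preictal,
        separation=separation,
    )


def _state_intervals(timeline: TimelineSpec) -> list[tuple[float, float, str]]:
    """Partition [0, duration) into labelled (start, end, state) pieces."""
    events: list[tuple[float, float, str]] = []
    prev_ictal_end = -np.inf
    for on, off in timeline.seizure_intervals():
        pre_start = on - timeline.preictal_len_s
        if pre_start < prev_ictal_end:
            raise ValueError(
                f"preictal window of seizure at {on:.1f} s overlaps the "
                "previous seizure; respace the timeline"
            )
        events.append((max(0.0, pre_start), on, "preictal"))
        events.append((on, off, "ictal"))
        prev_ictal_end = off
    out: list[tuple[float, float, str]] = []
    t = 0.0
    for s, e, state in events:
        if s > t:
            out.append((t, s, "interictal"))
        out.append((s, e, state))
        t = e
    if t < timeline.duration_s:
        out.append((t, timeline.duration_s, "interictal"))
    return out


def simulate_recording(timeline: TimelineSpec,
                       spec: StateCovarianceSpec
                       ) -> tuple[Recording, list[SeizureAnnotation]]:
    """Draw one continuous recording over the whole timeline.

    Samples are zero-mean Gaussian, coloured per state: interictal
    covariance outside preictal windows, preictal covariance in
    ``[onset - preictal_len, onset)``, and the preictal covariance scaled by
    :data:`ICTAL_BURST_FACTOR` inside seizures. Fully determined by
    ``timeline.seed``.

    Timelines with gaps must go through :func:`simulate_record_set`, which
    excises the gaps from the coverage map by splitting into records.
    """
    if timeline.gap_intervals:
        raise ValueError(
            "timeline declares gaps; use simulate_record_set to excise them"
        )
    rng = np.random.default_rng(timeline.seed)
    n = spec.n_channels
    total = int(round(timeline.duration_s * timeline.fs))
    chol = {
        "interictal": np.linalg.cholesky(spec.interictal_cov),
        "preictal": np.linalg.cholesky(spec.preictal_cov),
        "ictal": np.linalg.cholesky(ICTAL_BURST_FACTOR * spec.preictal_cov),
    }
    signal = np.empty((n, total))
    for s, e, state in _state_intervals(timeline):
        i0, i1 = int(round(s * timeline.fs)), int(round(e * timeline.fs))
        i1 = min(i1, total)
        if i1 <= i0:
            continue
        signal[:, i0:i1] = chol[state] @ rng.standard_normal((n, i1 - i0))
    rec = Recording(
        signal=signal,
        fs=timeline.fs,
        channel_labels=[f"SYN{i:02d}" for i in range(n)],
        start_time=0.0,
        record_id="synthetic",
    )
    anns = [
        SeizureAnnotation(record_id="synthetic", onset_s=on, offset_s=off)
        for on, off in timeline.seizure_intervals()
    ]
    return rec, anns


def simulate_record_set(timeline: TimelineSpec, spec: StateCovarianceSpec,
                        record_len_s: float | None = None,
                        patient_id: str = "synth") -> RecordSet:
    """Simulate a timeline and split it into a :class:`RecordSet`.

    The continuous signal is cut at gap boundaries (gaps are dropped from
    coverage, becoming "missing hours") and additionally every
    ``record_len_s`` seconds, emulating CHB-MIT's fixed-length records.
    Seizure annotations are assigned to the record containing them; a
    seizure straddling a cut is an error (respace the timeline).
    """
    gapless = TimelineSpec(
        duration_s=timeline.duration_s,
        seizure_onsets_s=list(timeline.seizure_onsets_s),
        seizure_durations_s=list(timeline.seizure_durations_s),
        preictal_len_s=timeline.preictal_len_s,
        gap_intervals=[],
        fs=timeline.fs,
        seed=timeline.seed,
    )
    full, _ = simulate_recording(gapless, spec)

    # coverage = [0, duration) minus gaps, then chopped to record_len_s
    pieces: list[tuple[float, float]] = []
    t = 0.0
    for gs, ge in sorted(timeline.gap_intervals):
        if gs > t:
            pieces.append((t, gs))
        t = ge
    if t < timeline.duration_s:
        pieces.append((t, timeline.duration_s))
    if record_len_s is not None:
        chopped = []
        for s, e in pieces:
            edges = np.arange(s, e, record_len_s)
            for a in edges:
                chopped.append((a, min(a + record_len_s, e)))
        pieces = chopped

    recordings = []
    annotations = []
    fs = timeline.fs
    for k, (s, e) in enumerate(pieces):
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        rid = f"{patient_id}_{k:02d}"
        recordings.append(
            Recording(
                signal=full.signal[:, i0:i1],
                fs=fs,
                channel_labels=list(full.channel_labels),
                start_time=s,
                record_id=rid,
            )
        )
    for on, off in timeline.seizure_intervals():
        placed = False
        for rec in recordings:
            if rec.start_time <= on and off <= rec.end_time + 1e-9:
                annotations.append(
                    SeizureAnnotation(
                        record_id=rec.record_id,
                        onset_s=on - rec.start_time,
                        offset_s=off - rec.start_time,
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"seizure [{on}, {off}) straddles a record/gap boundary"
            )
    return RecordSet(patient_id=patient_id, recordings=recordings,
                     annotations=annotations)


def demo_record_set(n_records: int = 6, record_len_s: float = 600.0,
                    n_channels: int = 8, separation: float = 1.5,
                    fs: float = 256.0, preictal_len_s: float = 180.0,
                    seizure_in_every: int = 2, seed: int = 0) -> RecordSet:
    """A ready-made multi-record patient for demos and end-to-end runs.

    Every ``seizure_in_every``-th record carries one 30 s seizure placed so
    its full preictal window is inside the record; the remaining records are
    seizure-free (supplying interictal training data).
    """
    duration = n_records * record_len_s
    onsets = []
    for k in range(n_records):
        if k % seizure_in_every == 1:
            onsets.append(k * record_len_s + record_len_s - 120.0)
    timeline = TimelineSpec(
        duration_s=duration,
        seizure_onsets_s=onsets,
        seizure_durations_s=[30.0] * len(onsets),
        preictal_len_s=preictal_len_s,
        fs=fs,
        seed=seed,
    )
    spec = make_state_covariances(n_channels, separation, seed=seed + 104729)
    return simulate_record_set(timeline, spec, record_len_s=record_len_s,
                               patient_id="synth")
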
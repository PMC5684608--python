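"""Reading scalp-EEG recordings and seizure annotations.

Supports CHB-MIT-style data: one EDF file per record plus a per-patient
summary text file declaring seizure onset/offset seconds. A portable
``.npz`` fixture container lets tests and the synthetic generator round-trip
recordings without any download.

Conventions used throughout the package: times are in seconds, intervals are
half-open ``[start, end)``, sample indices are 0-based, and each patient's
records live on a single global clock so that rules spanning record
boundaries (postictal merging, missing-hour margins) have unambiguous
arithmetic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger("preictal")

#: Major version of the .npz fixture container. Readers refuse newer majors.
FIXTURE_MAJOR_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Data violates a structural invariant (e.g. onset >= offset)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Recording:
    """One multichannel EEG record.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Channel-major signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique electrode names, in stored channel order.
    start_time : float
        Start of the record on the patient's global clock (seconds).
    record_id : str
        Identifier, conventionally the file stem.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.n_channels < 2:
            raise ValidationError("a recording needs at least 2 channels")
        if len(self.channel_labels) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique (harmonize first)")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s


@dataclass
class SeizureAnnotation:
    """One seizure marked within a record, in record-relative seconds."""

    record_id: str
    onset_s: float
    offset_s: float
    merged: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValidationError(
                f"seizure must satisfy 0 <= onset < offset, got "
                f"[{self.onset_s}, {self.offset_s}] in record {self.record_id!r}"
            )


@dataclass(frozen=True)
class GlobalSeizure:
    """A seizure resolved onto the global clock."""

    onset: float
    offset: float
    excluded: bool = False
    merged: bool = False


@dataclass
class RecordSet:
    """All records of one patient on a shared global timeline."""

    patient_id: str
    recordings: list[Recording]
    annotations: list[SeizureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        recs = sorted(self.recordings, key=lambda r: r.start_time)
        for a, b in zip(recs, recs[1:]):
            if b.start_time < a.end_time - 1e-9:
                raise ValidationError(
                    f"recordings {a.record_id!r} and {b.record_id!r} overlap in time"
                )
        self.recordings = recs
        known = {r.record_id for r in recs}
        for ann in self.annotations:
            if ann.record_id not in known:
                log.warning(
                    "annotation for unknown record %r kept but unmatched",
                    ann.record_id,
                )

    # -- timeline geometry --------------------------------------------------

    def coverage(self) -> list[tuple[float, float]]:
        """Recorded intervals ``[start, end)`` on the global clock."""
        return [(r.start_time, r.end_time) for r in self.recordings]

    def gaps(self) -> list[tuple[float, float]]:
        """Missing intervals between consecutive records (the coverage complement)."""
        cov = self.coverage()
        out = []
        for (_, e0), (s1, _) in zip(cov, cov[1:]):
            if s1 > e0 + 1e-9:
                out.append((e0, s1))
        return out

    def record_starts(self) -> dict[str, float]:
        return {r.record_id: r.start_time for r in self.recordings}

    def seizures_global(self, include_excluded: bool = True) -> list[GlobalSeizure]:
        starts = self.record_starts()
        out = []
        for ann in self.annotations:
            if ann.record_id not in starts:
                continue
            if ann.excluded and not include_excluded:
                continue
            t0 = starts[ann.record_id]
            out.append(
                GlobalSeizure(
                    onset=t0 + ann.onset_s,
                    offset=t0 + ann.offset_s,
                    excluded=ann.excluded,
                    merged=ann.merged,
                )
            )
        return sorted(out, key=lambda s: s.onset)

    def seizure_free_record_ids(self) -> set[str]:
        with_seizure = {a.record_id for a in self.annotations}
        return {r.record_id for r in self.recordings} - with_seizure


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------

def _harmonized_labels(labels: Sequence[str]) -> list[str]:
    """Suffix duplicate labels so they become unique, logging a warning."""
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            new = f"{lab}-{seen[lab]}"
            log.warning("duplicate channel label %r renamed to %r", lab, new)
            out.append(new)
        else:
            seen[lab] = 0
            out.append(lab)
    return out


def read_edf(path: str | Path) -> Recording:
    """Read one EDF file into a :class:`Recording` (microvolts).

    Channel order is preserved as stored; duplicate labels are suffixed to
    keep the uniqueness invariant. The record is placed at global time 0;
    :func:`layout_consecutively` or explicit start times position it later.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for broken headers
        raise FormatError(f"cannot parse EDF file {path.name}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts; store microvolts
    labels = _harmonized_labels(raw.ch_names)
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        start_time=0.0,
        record_id=path.stem,
    )


def layout_consecutively(recordings: Sequence[Recording],
                         gap_s: float = 0.0) -> list[Recording]:
    """Place records back-to-back on the global clock (optional uniform gap)."""
    out = []
    t = 0.0
    for rec in recordings:
        out.append(replace(rec, start_time=t))
        t += rec.duration_s + gap_s
    return out


# ---------------------------------------------------------------------------
# CHB-MIT summary annotations
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^\s*File Name\s*:\s*(\S+)", re.IGNORECASE)
_START_RE = re.compile(
    r"^\s*Seizure(?:\s+\d+)?\s+Start\s+Time\s*:\s*(\d+(?:\.\d+)?)", re.IGNORECASE
)
_END_RE = re.compile(
    r"^\s*Seizure(?:\s+\d+)?\s+End\s+Time\s*:\s*(\d+(?:\.\d+)?)", re.IGNORECASE
)


def read_chb_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Parse a CHB-MIT per-patient summary text file.

    The dialect interleaves ``File Name: chbXX_YY.edf`` lines with
    ``Seizure [k] Start Time: S seconds`` / ``Seizure [k] End Time: E seconds``
    pairs. Returns one annotation per declared seizure with ``record_id``
    equal to the file stem. Merging and exclusion are *not* applied here;
    see :func:`apply_seizure_policy`.
    """
    path = Path(path)
    annotations: list[SeizureAnnotation] = []
    current: str | None = None
    pending_start: float | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        m = _FILE_RE.match(line)
        if m:
            current = Path(m.group(1)).stem
            pending_start = None
            continue
        m = _START_RE.match(line)
        if m:
            pending_start = float(m.group(1))
            continue
        m = _END_RE.match(line)
        if m:
            end = float(m.group(1))
            if current is None or pending_start is None:
                raise FormatError(
                    f"{path.name}:{lineno}: seizure end without file/start context"
                )
            if pending_start >= end:
                raise ValidationError(
                    f"{path.name}:{lineno}: seizure start {pending_start} >= end {end}"
                )
            annotations.append(
                SeizureAnnotation(record_id=current, onset_s=pending_start,
                                  offset_s=end)
            )
            pending_start = None
    return annotations


# ---------------------------------------------------------------------------
# Seizure policy: postictal merging and insufficient-preictal exclusion
# ---------------------------------------------------------------------------

def apply_seizure_policy(
    annotations: Sequence[SeizureAnnotation],
    postictal_len: float,
    min_preictal: float,
    record_starts: dict[str, float] | None = None,
    coverage: Sequence[tuple[float, float]] | None = None,
) -> list[SeizureAnnotation]:
    """Merge postictally chained seizures and flag those lacking preictal data.

    A seizure whose onset falls within ``postictal_len`` seconds after the
    previous seizure's offset is merged into it (combined onset = first
    onset, offset = later offset, ``merged`` set). A seizure with less than
    ``min_preictal`` seconds of *recorded* data before its onset is marked
    ``excluded`` (it cannot supply a full preictal training interval).

    ``record_starts`` maps record_id to global start time; if omitted all
    onsets are taken as already global. ``coverage`` lists recorded global
    intervals; if omitted, recording is assumed continuous from the earliest
    record start. Idempotent: re-applying changes nothing.
    """
    if not annotations:
        return []
    starts = record_starts or {}

    def gtimes(a: SeizureAnnotation) -> tuple[float, float]:
        t0 = starts.get(a.record_id, 0.0)
        return t0 + a.onset_s, t0 + a.offset_s

    anns = sorted(annotations, key=lambda a: gtimes(a)[0])

    merged: list[SeizureAnnotation] = []
    for ann in anns:
        g_on, g_off = gtimes(ann)
        if merged:
            _, prev_off = gtimes(merged[-1])
            if g_on <= prev_off + postictal_len:
                prev = merged[-1]
                t0 = starts.get(prev.record_id, 0.0)
                new_off = max(prev.offset_s, g_off - t0)
                merged[-1] = replace(prev, offset_s=new_off, merged=True)
                log.info(
                    "merged seizure at %.1f s into previous (postictal chain)", g_on
                )
                continue
        merged.append(replace(ann))

    out = []
    for ann in merged:
        g_on, _ = gtimes(ann)
        window = (g_on - min_preictal, g_on)
        if coverage is not None:
            avail = _overlap_length(window, coverage)
        else:
            # assume continuous recording from the earliest record start
            origin = min(starts.values()) if starts else 0.0
            avail = min(min_preictal, max(0.0, g_on - origin))
        if avail + 1e-9 < min_preictal:
            if not ann.excluded:
                log.info(
                    "seizure at %.1f s excluded: only %.1f of %.1f s preictal "
                    "data recorded", g_on, avail, min_preictal,
                )
            ann = replace(ann, excluded=True,
                          exclusion_reason="insufficient_preictal")
        out.append(ann)
    return out


def _overlap_length(window: tuple[float, float],
                    intervals: Sequence[tuple[float, float]]) -> float:
    lo, hi = window
    total = 0.0
    for s, e in intervals:
        total += max(0.0, min(hi, e) - max(lo, s))
    return total


# ---------------------------------------------------------------------------
# Fixture container (.npz)
# ---------------------------------------------------------------------------

def write_fixture(recording: Recording,
                  annotations: Sequence[SeizureAnnotation],
                  path: str | Path) -> None:
    """Write a recording plus annotations to a versioned ``.npz`` container."""
    ann = annotations or []
    np.savez(
        Path(path),
        version=np.array([FIXTURE_MAJOR_VERSION, 0], dtype=np.int64),
        signal=recording.signal,
        fs=np.array(recording.fs),
        channel_labels=np.array(recording.channel_labels, dtype=np.str_),
        start_time=np.array(recording.start_time),
        record_id=np.array(recording.record_id, dtype=np.str_),
        ann_record_id=np.array([a.record_id for a in ann], dtype=np.str_),
        ann_onset=np.array([a.onset_s for a in ann], dtype=float),
        ann_offset=np.array([a.offset_s for a in ann], dtype=float),
        ann_merged=np.array([a.merged for a in ann], dtype=bool),
        ann_excluded=np.array([a.excluded for a in ann], dtype=bool),
        ann_reason=np.array([a.exclusion_reason for a in ann], dtype=np.str_),
    )


def read_fixture(path: str | Path) -> tuple[Recording, list[SeizureAnnotation]]:
    """Read a ``.npz`` fixture written by :func:`write_fixture`."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            version = z["version"]
            if int(version[0]) > FIXTURE_MAJOR_VERSION:
                raise FormatError(
                    f"fixture {path.name} has major version {int(version[0])}, "
                    f"reader supports <= {FIXTURE_MAJOR_VERSION}"
                )
            rec = Recording(
                signal=z["signal"],
                fs=float(z["fs"]),
                channel_labels=[str(s) for s in z["channel_labels"]],
                start_time=float(z["start_time"]),
                record_id=str(z["record_id"]),
            )
            anns = [
                SeizureAnnotation(
                    record_id=str(rid), onset_s=float(on), offset_s=float(off),
                    merged=bool(m), excluded=bool(x), exclusion_reason=str(rsn),
                )
                for rid, on, off, m, x, rsn in zip(
                    z["ann_record_id"], z["ann_onset"], z["ann_offset"],
                    z["ann_merged"], z["ann_excluded"], z["ann_reason"],
                )
            ]
    except FormatError:
        raise
    except (KeyError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read fixture {path.name}: {exc}") from exc
    return rec, anns
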
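"""Shared fixtures: synthetic record sets and a minimal EDF writer.

All fixture data is generated at test time; nothing binary is stored in the
repository. The EDF writer below emits just enough of the format (fixed
256-byte header, per-signal headers, int16 data records) to exercise the
EDF reader against synthetic signals.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

import preictal as p


def write_minimal_edf(path: Path, signal: np.ndarray, fs: float,
                      labels: list[str], phys_range: float = 1000.0) -> None:
    """Write a synthetic EDF file (int16, 1-second data records).

    Supports integer sampling rates and durations that are whole seconds;
    amplitudes are clipped to ±``phys_range`` microvolts.
    """
    n_ch, n_samp = signal.shape
    spr = int(round(fs))
    assert n_samp % spr == 0, "duration must be whole seconds"
    n_rec = n_samp // spr

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2000", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    sig_hdr = b"".join([
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(str(-phys_range), 8) for _ in labels),
        b"".join(pad(str(phys_range), 8) for _ in labels),
        b"".join(pad("-32768", 8) for _ in labels),
        b"".join(pad("32767", 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(spr), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ])
    clipped = np.clip(signal, -phys_range, phys_range)
    digital = np.round(
        (clipped + phys_range) / (2 * phys_range) * 65535 - 32768
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(struct.pack(f"<{n_ch * spr}h", *chunk.ravel()))


@pytest.fixture(scope="session")
def separable_record_set() -> p.RecordSet:
    """6 x 10-min records, 8 channels at 64 Hz, strong state separation."""
    return p.demo_record_set(n_records=6, record_len_s=600.0, n_channels=8,
                             separation=1.5, fs=64.0, seed=11)


@pytest.fixture(scope="session")
def inseparable_record_set() -> p.RecordSet:
    """Same layout but identical state covariances (separation 0)."""
    return p.demo_record_set(n_records=6, record_len_s=600.0, n_channels=8,
                             separation=0.0, fs=64.0, seed=11)


@pytest.fixture(scope="session")
def separable_loocv_report(separable_record_set) -> p.CrossValReport:
    """One shared leave-one-record-out run on the separable set."""
    return p.loocv_run(separable_record_set, p.RunConfig(seed=1))


def random_spd_pair(dim: int, rng: np.random.Generator):
    """Unit-trace-sum random SPD covariance pair (generic, not the generator's)."""
    def spd():
        a = rng.standard_normal((dim, dim))
        return a @ a.T + 0.1 * np.eye(dim)
    m1, m2 = spd(), spd()
    tr = np.trace(m1 + m2)
    return p.Covariance(m1 / tr), p.Covariance(m2 / tr)
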
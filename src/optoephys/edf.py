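"""Minimal EDF (European Data Format) export and import for LFP recordings.

Writing uses a small self-contained encoder (16-bit EDF, one data record per
second, physical unit uV); reading goes through :mod:`mne`, which also serves
as the round-trip cross-check for the writer.
"""

from __future__ import annotations

import warnings
from datetime import datetime
from pathlib import Path

import numpy as np

from .errors import DataError
from .lfp import LFPRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: LFPRecording, path: str | Path) -> None:
    """Write a recording to EDF with one signal per channel.

    EDF stores an integer number of fixed-duration data records (1 s here),
    so the sampling rate must be an integer and a trailing partial second is
    dropped with a warning.
    """
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise DataError(f"EDF export needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise DataError("recording shorter than one 1 s EDF data record")
    if n_records * fs != rec.n_samples:
        warnings.warn(
            f"dropping {rec.n_samples - n_records * fs} trailing samples "
            "(EDF records are whole seconds)",
            stacklevel=2,
        )
    data = rec.data[:, : n_records * fs]
    n_sig = data.shape[0]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid a zero physical span for constant channels
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)

    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # patient id
            _field("Startdate X X X X", 80),  # recording id
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_sig)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_sig), 4),
        ]
    )
    per_sig = [
        b"".join(_field(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_field("uV", 8) for _ in range(n_sig)),
        b"".join(_field(f"{phys_min[i]:.6g}", 8) for i in range(n_sig)),
        b"".join(_field(f"{phys_max[i]:.6g}", 8) for i in range(n_sig)),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_sig)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_sig)),
        b"".join(_field("", 80) for _ in range(n_sig)),
        b"".join(_field(str(fs), 8) for _ in range(n_sig)),
        b"".join(_field("", 32) for _ in range(n_sig)),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for block in per_sig:
            f.write(block)
        # data records: per record, all samples of signal 1, then signal 2, ...
        records = digital.reshape(n_sig, n_records, fs)
        for r in range(n_records):
            for s in range(n_sig):
                f.write(records[s, r].tobytes())


def read_edf(path: str | Path) -> LFPRecording:
    """Read an EDF file into an :class:`LFPRecording` (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne reports Volts for voltage channels; recordings are in microvolts
    data = raw.get_data() * 1e6
    return LFPRecording(
        channel_labels=list(raw.ch_names),
        fs_hz=float(raw.info["sfreq"]),
        data=data,
    )
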
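"""LFP containers, filtering, STFT spectrograms and robust outlier rejection.

The preprocessing chain mirrors a standard awake-rodent dual-site LFP
pipeline: band-pass filter (Chebyshev II, zero phase), short-time Fourier
transform with a Hann window (5 s / 50 % overlap for whole-session
spectrograms, 1 s bins for optogenetic trials), removal of 59-61 Hz line
noise by nearest-neighbour fill, and a two-stage spectrogram outlier
rejection: a global mean + 4 SD screen on the mean-power time series
followed by a sliding-window 5 x MAD screen over 5 min windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .errors import DataError, ParameterError
from .filters import bandpass_filtfilt

logger = logging.getLogger(__name__)

# scaling that turns a MAD into a consistent estimate of the SD of a normal
MAD_TO_SD = 1.4826


@dataclass
class LFPRecording:
    """Multichannel LFP signal in microvolts.

    data has shape (n_channels, n_samples); all channels share ``fs_hz``
    and start at ``start_time_s``.
    """

    channel_labels: list[str]
    fs_hz: float
    data: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs_hz <= 0:
            raise DataError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.data.shape[0] != len(self.channel_labels):
            raise DataError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise DataError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.data[i]


@dataclass
class Spectrogram:
    """One-sided power spectrogram: ``power`` is (n_times, n_freqs), uV^2/Hz."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray
    window_s: float
    overlap_frac: float
    channel_label: str = ""
    outlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times_s.size, self.freqs_hz.size):
            raise DataError(
                f"power shape {self.power.shape} != "
                f"({self.times_s.size}, {self.freqs_hz.size})"
            )
        if np.any(self.power < 0):
            raise DataError("negative power")
        if np.any(np.diff(self.times_s) <= 0) or np.any(np.diff(self.freqs_hz) <= 0):
            raise DataError("time/frequency bins must be strictly increasing")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.times_s.size, dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
            if self.outlier_mask.size != self.times_s.size:
                raise DataError("outlier_mask length must match number of time bins")

    def mean_power_series(self) -> np.ndarray:
        """Mean power across frequencies, one value per time bin."""
        return self.power.mean(axis=1)


# ---------------------------------------------------------------------------
# filtering and time-frequency decomposition
# ---------------------------------------------------------------------------

def bandpass(rec: LFPRecording, low_hz: float, high_hz: float, order: int = 4) -> LFPRecording:
    """Zero-phase Chebyshev II band-pass of every channel.

    Defaults reproduce the session-level 1-250 Hz cleanup; optogenetic
    sessions use (3, 300) where the sampling rate allows.
    """
    filtered = bandpass_filtfilt(rec.data, low_hz, high_hz, rec.fs_hz, order=order)
    return replace(rec, data=filtered)


def compute_stft(
    rec: LFPRecording,
    channel: str | None = None,
    window_s: float = 5.0,
    overlap_frac: float = 0.5,
) -> Spectrogram:
    """One-sided Hann-window power spectrogram of one channel.

    Frequency resolution is 1/window_s and the hop is
    window_s * (1 - overlap_frac).  The 5 s / 50 % default serves
    whole-session spectrograms; optogenetic trials use 1 s bins so the
    +/-1 Hz quantification band contains exactly three bins.
    """
    if channel is None:
        channel = rec.channel_labels[0]
    x = rec.channel(channel)
    nperseg = int(round(window_s * rec.fs_hz))
    if nperseg < 2:
        raise ParameterError(f"window_s={window_s} spans {nperseg} samples (< 2)")
    if not (0 <= overlap_frac < 1):
        raise ParameterError(f"overlap_frac={overlap_frac} must be in [0, 1)")
    if x.size < nperseg:
        raise DataError(
            f"recording ({x.size} samples) shorter than one window ({nperseg})"
        )
    noverlap = int(round(nperseg * overlap_frac))
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=rec.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(
        times_s=rec.start_time_s + times,
        freqs_hz=freqs,
        power=sxx.T,
        window_s=window_s,
        overlap_frac=overlap_frac,
        channel_label=channel,
    )


def remove_line_noise(
    spec: Spectrogram, band: tuple[float, float] = (59.0, 61.0)
) -> Spectrogram:
    """Blank power-line bins and fill with the nearest out-of-band bin.

    Every frequency bin whose centre falls in ``band`` (closed) is replaced,
    per time bin, by the value of the nearest bin outside the band.
    """
    lo, hi = band
    in_band = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not np.any(in_band):
        warnings.warn(
            f"no frequency bins inside {band} Hz; spectrogram returned unchanged",
            stacklevel=2,
        )
        return spec
    if np.all(in_band):
        raise ParameterError(f"band {band} covers every frequency bin")
    out_idx = np.flatnonzero(~in_band)
    power = spec.power.copy()
    for j in np.flatnonzero(in_band):
        nearest = out_idx[np.argmin(np.abs(spec.freqs_hz[out_idx] - spec.freqs_hz[j]))]
        power[:, j] = power[:, nearest]
    logger.info("line-noise fill: %d bins in %s Hz replaced", int(in_band.sum()), band)
    return replace(spec, power=power, outlier_mask=spec.outlier_mask.copy())


# ---------------------------------------------------------------------------
# two-stage outlier rejection
# ---------------------------------------------------------------------------

def _stage1_flags(series: np.ndarray, k: float) -> np.ndarray:
    mu = series.mean()
    sd = series.std()
    return series > mu + k * sd


def _stage2_flags(
    series: np.ndarray, times: np.ndarray, mad_k: float, window_s: float
) -> np.ndarray:
    """Sliding-window MAD screen, one-sided high, window centred per bin."""
    half = window_s / 2.0
    flags = np.zeros(series.size, dtype=bool)
    for i, t in enumerate(times):
        w = series[(times >= t - half) & (times <= t + half)]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if mad == 0:
            continue  # silent/constant window: flag nothing
        flags[i] = series[i] > med + mad_k * MAD_TO_SD * mad
    return flags


def detect_outliers(
    spec: Spectrogram,
    global_k: float = 4.0,
    mad_k: float = 5.0,
    window_min: float = 5.0,
) -> Spectrogram:
    """Two-stage spectrogram artifact rejection.

    Stage 1 works on the mean power across frequencies: bins exceeding
    mean + ``global_k`` x SD are flagged and their power columns replaced by
    the per-frequency median over the non-flagged bins.  Stage 2 slides a
    ``window_min``-minute window over the cleaned mean-power series and flags
    bins exceeding the window median + ``mad_k`` x scaled MAD (one-sided,
    high); flagged bins are forward-filled from the most recent clean bin
    (first-bin fallback: the nearest following clean bin).  The returned
    mask is the union of both stages.
    """
    series = spec.mean_power_series()
    flags1 = _stage1_flags(series, global_k)
    power = spec.power.copy()
    if np.all(flags1):
        raise DataError("every time bin flagged by the global screen")
    if np.any(flags1):
        col_med = np.median(power[~flags1], axis=0)
        power[flags1] = col_med
    logger.info("outlier stage 1: %d/%d bins flagged", int(flags1.sum()), flags1.size)

    span_s = spec.times_s[-1] - spec.times_s[0] if spec.times_s.size > 1 else 0.0
    window_s = window_min * 60.0
    if span_s < window_s:
        warnings.warn(
            f"spectrogram spans {span_s:.0f} s < {window_s:.0f} s; "
            "sliding-window stage skipped",
            stacklevel=2,
        )
        flags2 = np.zeros_like(flags1)
    else:
        series1 = power.mean(axis=1)
        flags2 = _stage2_flags(series1, spec.times_s, mad_k, window_s)
        clean = ~(flags1 | flags2)
        if not np.any(clean):
            raise DataError("every time bin flagged after both stages")
        for i in np.flatnonzero(flags2):
            prev = np.flatnonzero(clean[:i])
            if prev.size:
                power[i] = power[prev[-1]]
            else:
                nxt = np.flatnonzero(clean[i + 1:])
                power[i] = power[i + 1 + nxt[0]]
        logger.info(
            "outlier stage 2: %d/%d bins flagged", int(flags2.sum()), flags2.size
        )

    mask = flags1 | flags2
    return replace(spec, power=power, outlier_mask=mask)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_recording_text(path: str | Path) -> LFPRecording:
    """Read a delimited-text recording: a ``time_s`` column then one column
    per channel (header row required; sampling rate inferred from time)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise DataError(f"{path}: expected columns time_s, <ch1>, ...")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise DataError(f"{path}: time stamps are not uniformly spaced")
    labels = [c for c in df.columns if c != "time_s"]
    return LFPRecording(
        channel_labels=labels,
        fs_hz=1.0 / dt[0],
        data=df[labels].to_numpy(dtype=float).T,
        start_time_s=float(t[0]),
    )


def load_recording(path: str | Path) -> LFPRecording:
    """Dispatch on extension: ``.edf`` via the EDF reader, else delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        from .edf import read_edf

        return read_edf(path)
    return load_recording_text(path)


def save_spectrogram_h5(spec: Spectrogram, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=spec.power)
        f.create_dataset("times_s", data=spec.times_s)
        f.create_dataset("freqs_hz", data=spec.freqs_hz)
        f.create_dataset("mask", data=spec.outlier_mask)
        f.attrs["window_s"] = spec.window_s
        f.attrs["overlap"] = spec.overlap_frac
        f.attrs["channel"] = spec.channel_label


def load_spectrogram_h5(path: str | Path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        return Spectrogram(
            times_s=f["times_s"][()],
            freqs_hz=f["freqs_hz"][()],
            power=f["power"][()],
            window_s=float(f.attrs["window_s"]),
            overlap_frac=float(f.attrs["overlap"]),
            channel_label=str(f.attrs["channel"]),
            outlier_mask=f["mask"][()],
        )
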
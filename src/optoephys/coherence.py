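"""Inter-regional phase coherence: PLV and imaginary PLV.

Instantaneous phase is taken from the analytic signal (Hilbert transform)
of the +/-1 Hz zero-phase band-passed recording at each stimulation
frequency.  For two phase series the phase locking value is

    PLV  = | <exp(i (phi_a - phi_b))>_t |
    iPLV = | Im <exp(i (phi_a - phi_b))>_t |

PLV is 1 for perfect locking and ~0 for independent phases; iPLV discards
the real (zero-lag) part of the mean phasor and is therefore insensitive to
instantaneous synchrony such as volume conduction.  Both are normalized per
frequency as the ratio of the stimulation window (0-120 s from onset) to
the 30 s pre-onset baseline, with repeats averaged within each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .errors import AlignmentError, DataError, ParameterError
from .filters import bandpass_filtfilt
from .lfp import LFPRecording
from .protocol import StimProtocol

EDGE_FRAC = 0.05  # fraction of samples flagged at each end (filter transients)


@dataclass
class PhaseSeries:
    """Instantaneous phase of a narrowband signal, radians in (-pi, pi]."""

    times_s: np.ndarray
    phase_rad: np.ndarray
    center_hz: float
    half_width_hz: float
    channel_label: str = ""
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        if self.times_s.size != self.phase_rad.size:
            raise DataError("times and phase must have equal length")
        if self.valid is None:
            n_edge = int(np.floor(EDGE_FRAC * self.times_s.size))
            v = np.ones(self.times_s.size, dtype=bool)
            if n_edge > 0:
                v[:n_edge] = False
                v[-n_edge:] = False
            self.valid = v


def narrowband_phase(
    rec: LFPRecording,
    channel: str,
    center_hz: float,
    half_width_hz: float = 1.0,
    filter_order: int = 2,
) -> PhaseSeries:
    """Phase of the analytic signal after a +/-hw zero-phase band-pass.

    The Chebyshev II design drops to order 2 for the default 2 Hz-wide band
    to stay numerically stable.  The outer 5 % of samples at each end are
    flagged invalid so filter transients never enter phase averages.
    """
    x = rec.channel(channel)
    min_samples = int(np.ceil(10.0 / center_hz * rec.fs_hz))
    if x.size < min_samples:
        raise ParameterError(
            f"recording ({x.size} samples) shorter than 10 cycles of {center_hz} Hz"
        )
    nb = bandpass_filtfilt(
        x, center_hz - half_width_hz, center_hz + half_width_hz, rec.fs_hz,
        order=filter_order,
    )
    phase = np.angle(hilbert(nb))
    return PhaseSeries(
        times_s=rec.times_s,
        phase_rad=phase,
        center_hz=center_hz,
        half_width_hz=half_width_hz,
        channel_label=channel,
    )


def _window_dphi(
    a: PhaseSeries, b: PhaseSeries, t_window: tuple[float, float] | None
) -> np.ndarray:
    if a.times_s.size != b.times_s.size or not np.allclose(a.times_s, b.times_s):
        raise AlignmentError("phase series are not on the same time base")
    if a.center_hz != b.center_hz or a.half_width_hz != b.half_width_hz:
        raise AlignmentError("phase series use different frequency bands")
    if t_window is None:
        sel = a.valid & b.valid
        if not sel.any():
            raise DataError("no interior samples")
        return a.phase_rad[sel] - b.phase_rad[sel]
    # windowed average: drop 5% of the window's own samples at each end,
    # so filter/edge transients never dominate short epoch windows
    t0, t1 = t_window
    idx = np.flatnonzero((a.times_s >= t0) & (a.times_s < t1))
    n_edge = int(np.floor(EDGE_FRAC * idx.size))
    idx = idx[n_edge : idx.size - n_edge]
    if idx.size == 0:
        raise DataError(f"no interior samples in window {t_window}")
    return a.phase_rad[idx] - b.phase_rad[idx]


def plv(a: PhaseSeries, b: PhaseSeries, t_window: tuple[float, float] | None = None) -> float:
    """Modulus of the time-averaged unit phasor of the phase difference."""
    dphi = _window_dphi(a, b, t_window)
    return float(np.abs(np.exp(1j * dphi).mean()))


def iplv(a: PhaseSeries, b: PhaseSeries, t_window: tuple[float, float] | None = None) -> float:
    """Absolute imaginary part of the mean phasor (zero-lag insensitive)."""
    dphi = _window_dphi(a, b, t_window)
    return float(np.abs(np.imag(np.exp(1j * dphi).mean())))


@dataclass
class CoherenceResult:
    """PLV/iPLV per frequency for baseline and stimulation windows."""

    freq_hz: float
    plv_base: float
    plv_stim: float
    iplv_base: float
    iplv_stim: float
    n_repeats: int
    phase_diff_base: np.ndarray
    phase_diff_stim: np.ndarray

    @property
    def plv_ratio(self) -> float:
        return self.plv_stim / self.plv_base if self.plv_base > 0 else np.nan

    @property
    def iplv_ratio(self) -> float:
        return self.iplv_stim / self.iplv_base if self.iplv_base > 0 else np.nan


def coherence_ratio(
    rec: LFPRecording,
    protocol: StimProtocol,
    freqs_hz: list[float] | None = None,
    channels: tuple[str, str] = ("BLA", "mPFC"),
    stim_window_s: tuple[float, float] = (0.0, 120.0),
    base_window_s: tuple[float, float] = (-30.0, 0.0),
    half_width_hz: float = 1.0,
    included: set[tuple[float, int]] | None = None,
) -> list[CoherenceResult]:
    """Stimulation/baseline PLV and iPLV ratios per drive frequency.

    PLV and iPLV are computed per repeat in epoch-relative windows, averaged
    across repeats within each window, then ratioed (baseline reference = 1).
    ``included`` optionally restricts repeats to (freq_hz, repeat_idx) pairs
    that survived the evoked-power inclusion screen.
    """
    if freqs_hz is None:
        freqs_hz = protocol.freqs_hz
    results = []
    for f in freqs_hz:
        pa = narrowband_phase(rec, channels[0], f, half_width_hz)
        pb = narrowband_phase(rec, channels[1], f, half_width_hz)
        plv_b, plv_s, iplv_b, iplv_s = [], [], [], []
        dphi_b, dphi_s = [], []
        for e in protocol:
            if e.freq_hz != f:
                continue
            if included is not None and (e.freq_hz, e.repeat_idx) not in included:
                continue
            bwin = (e.onset_s + base_window_s[0], e.onset_s + base_window_s[1])
            swin = (e.onset_s + stim_window_s[0],
                    min(e.onset_s + stim_window_s[1], e.offset_s))
            plv_b.append(plv(pa, pb, bwin))
            plv_s.append(plv(pa, pb, swin))
            iplv_b.append(iplv(pa, pb, bwin))
            iplv_s.append(iplv(pa, pb, swin))
            dphi_b.append(_wrap(_window_dphi(pa, pb, bwin)))
            dphi_s.append(_wrap(_window_dphi(pa, pb, swin)))
        if not plv_b:
            continue
        results.append(
            CoherenceResult(
                freq_hz=f,
                plv_base=float(np.mean(plv_b)),
                plv_stim=float(np.mean(plv_s)),
                iplv_base=float(np.mean(iplv_b)),
                iplv_stim=float(np.mean(iplv_s)),
                n_repeats=len(plv_b),
                phase_diff_base=np.concatenate(dphi_b),
                phase_diff_stim=np.concatenate(dphi_s),
            )
        )
    return results


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2 * np.pi)


def phase_histogram(result: CoherenceResult, n_bins: int = 36) -> pd.DataFrame:
    """Uniform-bin histogram of the phase difference over (-pi, pi].

    Counts sum to the number of interior samples in each window.
    """
    if n_bins < 4:
        raise ParameterError(f"n_bins must be >= 4, got {n_bins}")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    cb, _ = np.histogram(result.phase_diff_base, bins=edges)
    cs, _ = np.histogram(result.phase_diff_stim, bins=edges)
    return pd.DataFrame(
        {
            "bin_center_rad": 0.5 * (edges[:-1] + edges[1:]),
            "count_base": cb,
            "count_stim": cs,
        }
    )


def results_to_frame(results: list[CoherenceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for window, p, ip in (
            ("baseline", r.plv_base, r.iplv_base),
            ("stimulation", r.plv_stim, r.iplv_stim),
        ):
            rows.append(
                {
                    "freq_hz": r.freq_hz,
                    "window": window,
                    "plv": p,
                    "iplv": ip,
                    "plv_ratio": r.plv_ratio,
                    "iplv_ratio": r.iplv_ratio,
                    "n_samples": (
                        r.phase_diff_base.size if window == "baseline"
                        else r.phase_diff_stim.size
                    ),
                }
            )
    return pd.DataFrame(rows)
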
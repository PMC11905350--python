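"""Stimulation-evoked LFP power quantification.

For each stimulation epoch, band power within +/-1 Hz of the drive
frequency is averaged over the stimulation window (0-120 s from onset) and
the 30 s immediately preceding onset; their ratio quantifies entrainment.
The reported effect is ratio - 1, so "no change" sits at 0.  Repeats of a
frequency whose ratio deviates from the group mean by more than 2 SD are
excluded before averaging.  A generalized Morse wavelet transform provides
the visualization spectrogram; it never feeds the power quantification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .lfp import LFPRecording, Spectrogram
from .protocol import StimProtocol

logger = logging.getLogger(__name__)


@dataclass
class PowerRatioResult:
    """Evoked-power quantification for one stimulation epoch."""

    channel_label: str
    freq_hz: float
    repeat_idx: int
    stim_power: float
    base_power: float
    ratio: float  # stim/base; reported effect is ratio - 1 (baseline = 0)
    deviation_score: float = np.nan  # SDs from the group mean ratio
    included: bool = True
    valid: bool = True

    @property
    def ratio_minus_1(self) -> float:
        return self.ratio - 1.0


def band_power(
    spec: Spectrogram,
    center_hz: float,
    half_width_hz: float = 1.0,
    t_window: tuple[float, float] | None = None,
) -> float:
    """Mean power over bins in the closed band [center +/- hw] and the
    half-open time window [t0, t1)."""
    fsel = (spec.freqs_hz >= center_hz - half_width_hz) & (
        spec.freqs_hz <= center_hz + half_width_hz
    )
    if t_window is None:
        tsel = np.ones(spec.times_s.size, dtype=bool)
    else:
        t0, t1 = t_window
        tsel = (spec.times_s >= t0) & (spec.times_s < t1)
    if not fsel.any() or not tsel.any():
        raise DataError(
            f"no spectrogram bins in band {center_hz}+/-{half_width_hz} Hz, "
            f"window {t_window}"
        )
    return float(spec.power[np.ix_(tsel, fsel)].mean())


def power_ratio(
    spec: Spectrogram,
    protocol: StimProtocol,
    stim_window_s: tuple[float, float] = (0.0, 120.0),
    base_window_s: tuple[float, float] = (-30.0, 0.0),
    half_width_hz: float = 1.0,
) -> list[PowerRatioResult]:
    """Stimulation / baseline band power per epoch at the epoch's frequency.

    Windows are epoch-relative: baseline (-30, 0) is the 30 s immediately
    before onset.  The stimulation window is clipped at the epoch offset so
    shorter epochs are handled.  Epochs without enough pre-onset data are
    skipped with a warning; epochs with zero baseline power are marked
    invalid.
    """
    results = []
    # first sample covered by the spectrogram (bin centers sit half a
    # window after the data start)
    data_start = spec.times_s[0] - spec.window_s / 2.0
    for e in protocol:
        b0, b1 = e.onset_s + base_window_s[0], e.onset_s + base_window_s[1]
        s0 = e.onset_s + stim_window_s[0]
        s1 = min(e.onset_s + stim_window_s[1], e.offset_s)
        if b0 < data_start - 1e-9:
            warnings.warn(
                f"epoch at {e.onset_s} s: insufficient pre-onset data; skipped",
                stacklevel=2,
            )
            continue
        stim_p = band_power(spec, e.freq_hz, half_width_hz, (s0, s1))
        base_p = band_power(spec, e.freq_hz, half_width_hz, (b0, b1))
        if base_p <= 0:
            results.append(
                PowerRatioResult(
                    spec.channel_label, e.freq_hz, e.repeat_idx,
                    stim_p, base_p, np.nan, valid=False, included=False,
                )
            )
            continue
        results.append(
            PowerRatioResult(
                spec.channel_label, e.freq_hz, e.repeat_idx,
                stim_p, base_p, stim_p / base_p,
            )
        )
    return results


def inclusion_filter(
    results: list[PowerRatioResult], k: float = 2.0
) -> list[PowerRatioResult]:
    """Flag repeats deviating more than ``k`` SD from their group mean ratio.

    Groups are (channel, frequency); the SD is the population SD of the
    group's ratios and exclusion uses strict inequality, so boundary cases
    are retained.  Groups of one pass through included with a warning.
    """
    groups: dict[tuple[str, float], list[PowerRatioResult]] = {}
    for r in results:
        if r.valid:
            groups.setdefault((r.channel_label, r.freq_hz), []).append(r)
    for (ch, f), grp in groups.items():
        ratios = np.array([r.ratio for r in grp])
        if ratios.size == 1:
            warnings.warn(
                f"group ({ch}, {f} Hz) has a single repeat; retained", stacklevel=2
            )
            grp[0].deviation_score = 0.0
            grp[0].included = True
            continue
        mu, sd = ratios.mean(), ratios.std()
        for r in grp:
            r.deviation_score = (r.ratio - mu) / sd if sd > 0 else 0.0
            r.included = not (sd > 0 and abs(r.ratio - mu) > k * sd)
        n_out = sum(not r.included for r in grp)
        if n_out:
            logger.info("inclusion filter: %d/%d repeats excluded for (%s, %g Hz)",
                        n_out, len(grp), ch, f)
    return results


def average_repeats(results: list[PowerRatioResult]) -> pd.DataFrame:
    """Mean ratio over included repeats per (channel, frequency).

    Groups with zero included repeats are reported with NaN (missing),
    never zero.
    """
    groups: dict[tuple[str, float], list[PowerRatioResult]] = {}
    for r in results:
        groups.setdefault((r.channel_label, r.freq_hz), []).append(r)
    rows = []
    for (ch, f), grp in sorted(groups.items()):
        inc = [r.ratio for r in grp if r.included and r.valid]
        rows.append(
            {
                "channel": ch,
                "freq_hz": f,
                "mean_ratio": float(np.mean(inc)) if inc else np.nan,
                "mean_ratio_minus_1": float(np.mean(inc)) - 1.0 if inc else np.nan,
                "n_included": len(inc),
                "n_total": len(grp),
            }
        )
    return pd.DataFrame(rows)


def presentation_order_effect(
    results: list[PowerRatioResult], protocol: StimProtocol | None = None
) -> pd.DataFrame:
    """Mean ratio by presentation position per frequency.

    Exported for external statistical testing (the design predicts no order
    effect); no inferential statistic is computed here.
    """
    rows = [
        {
            "channel": r.channel_label,
            "freq_hz": r.freq_hz,
            "position": r.repeat_idx,
            "ratio": r.ratio,
        }
        for r in results
        if r.valid
    ]
    df = pd.DataFrame(rows)
    return (
        df.pivot_table(
            index=["channel", "freq_hz"], columns="position", values="ratio",
            aggfunc="mean",
        )
        .rename(columns=lambda p: f"position_{p}")
        .reset_index()
    )


def results_to_frame(results: list[PowerRatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": r.channel_label,
                "freq_hz": r.freq_hz,
                "repeat_idx": r.repeat_idx,
                "stim_power": r.stim_power,
                "base_power": r.base_power,
                "ratio": r.ratio,
                "ratio_minus_1": r.ratio_minus_1,
                "deviation_score": r.deviation_score,
                "included": r.included,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Morse wavelet visualization
# ---------------------------------------------------------------------------

def _morse_freq_domain(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Generalized Morse wavelet in the frequency domain, peak value 2."""
    psi = np.zeros_like(omega)
    pos = omega > 0
    w_peak = (beta / gamma) ** (1.0 / gamma)
    ln_psi = beta * np.log(omega[pos] / w_peak) - (omega[pos] ** gamma - w_peak**gamma)
    psi[pos] = 2.0 * np.exp(ln_psi)
    return psi


def morse_spectrogram(
    rec: LFPRecording,
    freq_range_hz: tuple[float, float],
    channel: str | None = None,
    n_freqs: int = 64,
    gamma: float = 3.0,
    beta: float = 20.0,
) -> Spectrogram:
    """Time-frequency magnitude via generalized Morse wavelets (gamma=3,
    beta=20), on a logarithmic frequency grid.  Visualization only; the
    power-ratio quantification always uses the 1 s-bin STFT.
    """
    lo, hi = freq_range_hz
    if not (0 < lo < hi < rec.fs_hz / 2):
        raise ParameterError(
            f"freq_range {freq_range_hz} must lie inside (0, {rec.fs_hz / 2}) Hz"
        )
    if channel is None:
        channel = rec.channel_labels[0]
    x = rec.channel(channel)
    n = x.size
    freqs = np.geomspace(lo, hi, n_freqs)
    xf = np.fft.fft(x)
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / rec.fs_hz)
    w_peak = (beta / gamma) ** (1.0 / gamma)
    mag = np.empty((n, n_freqs))
    for j, f in enumerate(freqs):
        scale = w_peak / (2 * np.pi * f)
        psi = _morse_freq_domain(scale * omega, gamma, beta)
        mag[:, j] = np.abs(np.fft.ifft(xf * psi))
    return Spectrogram(
        times_s=rec.times_s,
        freqs_hz=freqs,
        power=mag,
        window_s=0.0,
        overlap_frac=0.0,
        channel_label=channel,
    )
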
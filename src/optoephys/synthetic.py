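"""Ground-truth synthetic data for every stage of the pipeline.

Three generators emulate the study's recording designs:

* dual-site LFP (BLA, mPFC): 1/f^alpha background noise, stimulation-locked
  sinusoids at the drive frequencies (5/10/20/40 Hz, three pseudorandomized
  repeats of 120 s each by default) with a controllable phase lag between
  channels, an optional identical zero-lag component (volume-conduction
  stand-in), 60 Hz line noise, and injected half-sine artifacts;
* dopamine-sensor ΔF/F: quadratic photobleaching trend plus per-trial
  difference-of-exponentials transients (15 trials of 5 s stimulation every
  30 s at 20 frames/s) and Gaussian noise;
* 3CST nose trajectory: reflected random walk with zone stickiness and a
  side-bias drift, with ground-truth zone occupancy recorded.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import ArenaGeometry, BehaviorSession
from .errors import ConfigError
from .lfp import LFPRecording
from .photometry import PhotometrySession
from .protocol import StimEpoch, StimProtocol

ARTIFACT_DUR_S = 0.5  # half-sine artifact transient length


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def pseudorandom_schedule(
    freqs_hz=(5.0, 10.0, 20.0, 40.0),
    n_repeats: int = 3,
    stim_dur_s: float = 120.0,
    gap_s: float = 60.0,
    lead_in_s: float = 60.0,
    pulse_width_ms: float = 5.0,
    seed: int = 0,
) -> list[StimEpoch]:
    """Pseudorandomized epoch order: every frequency repeated ``n_repeats``
    times, separated by ``gap_s`` baseline (>= 30 s for the pre-stimulation
    window at defaults)."""
    rng = np.random.default_rng(seed)
    order = np.repeat(np.asarray(freqs_hz, dtype=float), n_repeats)
    rng.shuffle(order)
    counts: dict[float, int] = {}
    epochs = []
    t = lead_in_s
    for f in order:
        counts[f] = counts.get(f, 0) + 1
        epochs.append(
            StimEpoch(
                onset_s=t,
                offset_s=t + stim_dur_s,
                freq_hz=float(f),
                pulse_width_ms=pulse_width_ms,
                repeat_idx=counts[f],
            )
        )
        t += stim_dur_s + gap_s
    return epochs


@dataclass
class SyntheticLFPConfig:
    """Ground-truth dual-site LFP generator settings (amplitudes in uV)."""

    seed: int = 0
    duration_s: float | None = None  # default: schedule span + lead-in tail
    fs_hz: float = 1000.0
    noise_exponent: float = 1.0  # background power ~ 1/f^alpha
    noise_amp: float = 50.0  # RMS of the 1/f background per channel
    stim_freqs_hz: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0)
    stim_amp: float = 100.0
    stim_schedule: list[StimEpoch] | None = None
    waveform: str = "sine"  # sine | pulse (rectangular pulse train)
    phase_lag_rad: float = 0.0
    shared_zero_lag_amp: float = 0.0
    artifact_times_s: tuple[float, ...] = ()
    artifact_amp: float = 0.0
    line_noise_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.stim_schedule is None:
            self.stim_schedule = pseudorandom_schedule(
                self.stim_freqs_hz, seed=self.seed
            )
        if self.duration_s is None:
            last = max((e.offset_s for e in self.stim_schedule), default=0.0)
            self.duration_s = last + 60.0
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        f_req = max([*(e.freq_hz for e in self.stim_schedule), 61.0])
        if self.fs_hz <= 2 * f_req:
            raise ConfigError(
                f"fs_hz={self.fs_hz} must exceed twice max({f_req}) Hz"
            )
        for name in ("noise_amp", "stim_amp", "shared_zero_lag_amp",
                     "artifact_amp", "line_noise_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.waveform not in ("sine", "pulse"):
            raise ConfigError(f"waveform must be 'sine' or 'pulse', got {self.waveform!r}")
        eps = sorted(self.stim_schedule, key=lambda e: e.onset_s)
        for a, b in zip(eps, eps[1:]):
            if b.onset_s < a.offset_s:
                raise ConfigError(f"stim_schedule epochs overlap at {b.onset_s} s")
        for e in eps:
            if not (0 <= e.onset_s < e.offset_s <= self.duration_s):
                raise ConfigError(
                    f"stim_schedule epoch [{e.onset_s}, {e.offset_s}) outside "
                    f"[0, {self.duration_s})"
                )


def one_over_f_noise(
    n: int, fs_hz: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _drive_waveform(t: np.ndarray, freq_hz: float, phase_rad: float,
                    waveform: str, pulse_width_ms: float) -> np.ndarray:
    """Unit-amplitude stimulation-locked component at the drive frequency."""
    if waveform == "sine":
        return np.sin(2 * np.pi * freq_hz * t - phase_rad)
    # rectangular pulse train: pulses of pulse_width_ms at the drive rate
    shifted = t - phase_rad / (2 * np.pi * freq_hz)
    frac = np.mod(shifted, 1.0 / freq_hz)
    return (frac < pulse_width_ms / 1000.0).astype(float)


def generate_lfp_pair(config: SyntheticLFPConfig) -> tuple[LFPRecording, StimProtocol]:
    """Two-channel LFP ("BLA", "mPFC") plus its stimulation protocol.

    During each epoch a drive-frequency component is added to channel 1 and,
    shifted by ``phase_lag_rad``, to channel 2.  The shared zero-lag
    component is an identical 1/f trace added to both channels for the whole
    recording.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz

    ch1 = config.noise_amp * one_over_f_noise(n, config.fs_hz, config.noise_exponent, rng)
    ch2 = config.noise_amp * one_over_f_noise(n, config.fs_hz, config.noise_exponent, rng)
    if config.shared_zero_lag_amp > 0:
        shared = config.shared_zero_lag_amp * one_over_f_noise(
            n, config.fs_hz, config.noise_exponent, rng
        )
        ch1 += shared
        ch2 += shared

    for e in config.stim_schedule:
        sl = slice(int(round(e.onset_s * config.fs_hz)),
                   int(round(e.offset_s * config.fs_hz)))
        tt = t[sl] - e.onset_s
        ch1[sl] += config.stim_amp * _drive_waveform(
            tt, e.freq_hz, 0.0, config.waveform, e.pulse_width_ms
        )
        ch2[sl] += config.stim_amp * _drive_waveform(
            tt, e.freq_hz, config.phase_lag_rad, config.waveform, e.pulse_width_ms
        )

    if config.line_noise_amp > 0:
        line = config.line_noise_amp * np.sin(2 * np.pi * 60.0 * t)
        ch1 += line
        ch2 += line

    for t0 in config.artifact_times_s:
        sl = slice(int(round(t0 * config.fs_hz)),
                   min(int(round((t0 + ARTIFACT_DUR_S) * config.fs_hz)), n))
        tt = t[sl] - t0
        # broadband burst under a half-sine envelope: movement/EMG-like
        # transients keep their energy across the analysis band
        envelope = np.sin(np.pi * tt / ARTIFACT_DUR_S)
        burst = config.artifact_amp * envelope * rng.standard_normal(tt.size)
        ch1[sl] += burst
        ch2[sl] += burst

    rec = LFPRecording(
        channel_labels=["BLA", "mPFC"], fs_hz=config.fs_hz, data=np.vstack([ch1, ch2])
    )
    return rec, StimProtocol(list(config.stim_schedule))


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPhotometryConfig:
    """Dopamine-sensor session: 15 x (5 s stim every 30 s) at 20 frames/s."""

    seed: int = 0
    n_trials: int = 15
    trial_period_s: float = 30.0
    stim_dur_s: float = 5.0
    frame_rate_hz: float = 20.0
    first_onset_s: float = 30.0
    bleach_coeffs: tuple[float, float, float] = (-2e-7, -2e-4, 1.0)  # a t^2 + b t + c
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    transient_amp: float | tuple[float, ...] = 0.5
    amp_decay: float = 1.0  # per-trial multiplicative decay (depletion emulation)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.frame_rate_hz <= 0:
            raise ConfigError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.trial_period_s <= self.stim_dur_s:
            raise ConfigError(
                f"trial_period_s ({self.trial_period_s}) must exceed "
                f"stim_dur_s ({self.stim_dur_s})"
            )
        if not (0 < self.kernel_rise_s < self.kernel_decay_s):
            raise ConfigError("require 0 < kernel_rise_s < kernel_decay_s")

    @property
    def onsets_s(self) -> np.ndarray:
        return self.first_onset_s + self.trial_period_s * np.arange(self.n_trials)

    @property
    def duration_s(self) -> float:
        return float(self.onsets_s[-1] + self.trial_period_s)

    @property
    def trial_amps(self) -> np.ndarray:
        if np.isscalar(self.transient_amp):
            base = float(self.transient_amp) * np.ones(self.n_trials)
        else:
            base = np.asarray(self.transient_amp, dtype=float)
            if base.size != self.n_trials:
                raise ConfigError(
                    f"transient_amp length {base.size} != n_trials {self.n_trials}"
                )
        return base * self.amp_decay ** np.arange(self.n_trials)


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials sensor kernel, peak-normalized to 1."""
    tp = np.maximum(t, 0.0)  # kernel is causal; exp(0)-exp(0)=0 handles t<=0
    k = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def kernel_integral(rise_s: float, decay_s: float) -> float:
    """Closed-form area of the peak-normalized kernel."""
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return (decay_s - rise_s) / peak


def generate_photometry(config: SyntheticPhotometryConfig) -> PhotometrySession:
    """ΔF/F trace = quadratic bleach trend + per-trial transients + noise."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.frame_rate_hz))
    t = np.arange(n) / config.frame_rate_hz
    a, b, c = config.bleach_coeffs
    trend = a * t**2 + b * t + c

    transients = np.zeros(n)
    for onset, amp in zip(config.onsets_s, config.trial_amps):
        transients += amp * transient_kernel(
            t - onset, config.kernel_rise_s, config.kernel_decay_s
        )
    noise = config.noise_sd * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
    trace = trend + transients + noise

    events = [(float(o), float(o + config.stim_dur_s)) for o in config.onsets_s]
    return PhotometrySession(
        frame_rate_hz=config.frame_rate_hz,
        roi_traces=trace[None, :],
        events=events,
        roi_ids=["roi0"],
        ground_truth={
            "trend": trend,
            "transients": transients,
            "trial_amps": config.trial_amps,
            "kernel_integral": kernel_integral(
                config.kernel_rise_s, config.kernel_decay_s
            ),
        },
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBehaviorConfig:
    """Reflected-random-walk nose trajectory in the 3CST arena.

    ``side_bias`` in [0, 1] tilts the walk toward (``> 0.5``) or away from
    (``< 0.5``) the stimulation-side cup; 0.5 is unbiased.  ``zone_stickiness``
    damps steps inside an interaction zone, producing dwell episodes.
    """

    seed: int = 0
    duration_s: float = 600.0
    sample_rate_hz: float = 25.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    stim_side: str = "left"
    side_bias: float = 0.5
    step_sd_cm: float = 2.0
    zone_stickiness: float = 0.85
    drift_gain_cm: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.side_bias <= 1.0):
            raise ConfigError(f"side_bias must be in [0, 1], got {self.side_bias}")
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if self.sample_rate_hz <= 0:
            raise ConfigError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.stim_side not in ("left", "right"):
            raise ConfigError(f"stim_side must be left|right, got {self.stim_side!r}")
        if not (0.0 <= self.zone_stickiness < 1.0):
            raise ConfigError(
                f"zone_stickiness must be in [0, 1), got {self.zone_stickiness}"
            )


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def generate_trajectory(config: SyntheticBehaviorConfig) -> BehaviorSession:
    """Nose trajectory with recorded ground-truth zone occupancy."""
    rng = np.random.default_rng(config.seed)
    g = config.arena
    n = int(round(config.duration_s * config.sample_rate_hz))
    dt = 1.0 / config.sample_rate_hz
    cups = {s: np.array(g.cup_center(s)) for s in ("left", "right")}
    r_zone = g.zone_radius_cm

    drift_mag = 2.0 * (config.side_bias - 0.5) * config.drift_gain_cm
    target = cups[config.stim_side]

    pos = np.array([g.width_cm / 2.0, g.depth_cm / 2.0])
    xs = np.empty(n)
    ys = np.empty(n)
    steps = rng.standard_normal((n, 2)) * config.step_sd_cm
    for i in range(n):
        in_zone = any(
            np.hypot(*(pos - cups[s])) <= r_zone for s in ("left", "right")
        )
        scale = (1.0 - config.zone_stickiness) if in_zone else 1.0
        to_target = target - pos
        dist = np.hypot(*to_target)
        drift = drift_mag * to_target / dist if dist > 1e-9 else 0.0
        pos = pos + scale * (steps[i] + drift)
        pos[0] = _reflect(np.array([pos[0]]), 0.0, g.width_cm)[0]
        pos[1] = _reflect(np.array([pos[1]]), 0.0, g.depth_cm)[0]
        xs[i], ys[i] = pos

    time_s = np.arange(n) * dt
    truth = {}
    for s in ("left", "right"):
        inside = np.hypot(xs - cups[s][0], ys - cups[s][1]) <= r_zone
        truth[s] = float(inside.sum() * dt)
    return BehaviorSession(
        time_s=time_s,
        nose_x_cm=xs,
        nose_y_cm=ys,
        stim_side=config.stim_side,
        ground_truth={"time_in_zone": truth},
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_lfp_text(rec: LFPRecording, path: str | Path) -> None:
    """Delimited text: time_s then one column per channel."""
    df = pd.DataFrame({"time_s": rec.times_s})
    for i, lbl in enumerate(rec.channel_labels):
        df[lbl] = rec.data[i]
    df.to_csv(path, index=False, float_format="%.6f")


def save_trajectory_with_arena(
    session: BehaviorSession, traj_path: str | Path, arena_path: str | Path,
    geometry: ArenaGeometry | None = None,
) -> None:
    from .behavior import save_trajectory

    save_trajectory(session, traj_path)
    write_arena_yaml(geometry or ArenaGeometry(), arena_path)


def write_arena_yaml(geometry: ArenaGeometry, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(
            {
                "width_cm": geometry.width_cm,
                "depth_cm": geometry.depth_cm,
                "cup_radius_cm": geometry.cup_radius_cm,
                "zone_margin_cm": geometry.zone_margin_cm,
                "cup_left_cm": list(geometry.cup_left_cm),
                "cup_right_cm": list(geometry.cup_right_cm),
            },
            f,
        )


def load_arena_yaml(path: str | Path) -> ArenaGeometry:
    with open(path) as f:
        d = yaml.safe_load(f)
    if d.get("cup_left_cm") is not None:
        d["cup_left_cm"] = tuple(d["cup_left_cm"])
    if d.get("cup_right_cm") is not None:
        d["cup_right_cm"] = tuple(d["cup_right_cm"])
    return ArenaGeometry(**d)
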
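"""Dopamine-sensor (GRAB-DA style) trial analysis of ROI ΔF/F traces.

A 10 min head-fixed session delivers 15 optogenetic pulse trains (40 Hz,
5 s) every 30 s while fluorescence is imaged at 20 frames per second.  The
pipeline is: quadratic detrend (photobleaching), normalization to the mean
pre-stimulation baseline (baseline maps to 1), parsing into per-trial
windows, per-second binning of the stimulation window, and a session
average that keeps trials as the observational unit (dopamine depletion
makes trials within a session dependent on their predecessors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, NormalizationError


@dataclass
class PhotometrySession:
    """ROI ΔF/F traces with stimulation events.

    roi_traces has shape (n_rois, n_frames), unitless ΔF/F; events are
    (onset_s, offset_s) stimulation epochs.  ``ground_truth`` is populated
    only by the synthetic generator.
    """

    frame_rate_hz: float
    roi_traces: np.ndarray
    events: list[tuple[float, float]]
    roi_ids: list[str] = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.roi_traces = np.atleast_2d(np.asarray(self.roi_traces, dtype=float))
        if self.frame_rate_hz <= 0:
            raise DataError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i}" for i in range(self.roi_traces.shape[0])]
        if len(self.roi_ids) != self.roi_traces.shape[0]:
            raise DataError("roi_ids length must match number of traces")
        span = self.roi_traces.shape[1] / self.frame_rate_hz
        for onset, offset in self.events:
            if not (0 <= onset < offset <= span + 1e-9):
                raise DataError(
                    f"event ({onset}, {offset}) outside session span [0, {span:.1f}] s"
                )

    @property
    def n_frames(self) -> int:
        return self.roi_traces.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class TrialMatrix:
    """Trials x frames of baseline-normalized response, aligned at stim onset.

    Rows are renormalized so each trial's pre-window averages exactly 1.
    """

    data: np.ndarray  # (n_trials, n_frames)
    frame_rate_hz: float
    pre_s: float
    post_s: float
    stim_dur_s: float
    onsets_s: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        """Frame times relative to stimulation onset."""
        return -self.pre_s + np.arange(self.data.shape[1]) / self.frame_rate_hz


def detrend_quadratic(trace: np.ndarray) -> np.ndarray:
    """Remove a least-squares second-degree polynomial trend.

    Models photobleaching across the session; the fit spans the full trace.
    """
    trace = np.asarray(trace, dtype=float)
    bad = np.flatnonzero(~np.isfinite(trace))
    if bad.size:
        raise DataError(f"non-finite frames at indices {bad[:10].tolist()}")
    if trace.size < 3:
        raise DataError(f"need >= 3 frames for a quadratic fit, got {trace.size}")
    t = np.arange(trace.size, dtype=float)
    # scale to [-1, 1] for a well-conditioned Vandermonde
    ts = 2 * t / (trace.size - 1) - 1
    coeffs = np.polynomial.polynomial.polyfit(ts, trace, 2)
    return trace - np.polynomial.polynomial.polyval(ts, coeffs)


def _baseline_mask(
    n_frames: int, events: list[tuple[float, float]], frame_rate_hz: float, pre_s: float
) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for onset, _ in events:
        i1 = int(round(onset * frame_rate_hz))
        i0 = int(round((onset - pre_s) * frame_rate_hz))
        if i0 < 0:
            continue
        mask[i0:i1] = True
    if not mask.any():
        raise DataError("no pre-stimulation baseline frames available")
    return mask


def normalize_to_baseline(
    trace: np.ndarray,
    events: list[tuple[float, float]],
    frame_rate_hz: float,
    pre_s: float = 5.0,
    baseline_offset: float = 0.0,
) -> np.ndarray:
    """Divide by the mean over the union of pre-stimulation windows.

    A detrended ΔF/F trace is near zero-mean, so direct division is
    unstable; callers pass the pre-stimulation mean of the raw trace as
    ``baseline_offset``, which is added back before dividing.  Baseline
    level maps to 1.
    """
    trace = np.asarray(trace, dtype=float) + baseline_offset
    mask = _baseline_mask(trace.size, events, frame_rate_hz, pre_s)
    divisor = trace[mask].mean()
    if divisor <= 0:
        raise NormalizationError(
            f"baseline divisor {divisor:.4g} is not positive; "
            "check baseline_offset / input scale"
        )
    return trace / divisor


def preprocess_session(session: PhotometrySession, pre_s: float = 5.0) -> np.ndarray:
    """Detrend + baseline-normalize each ROI, then average ROIs equally.

    The pipeline order (detrend before normalize) is fixed: normalizing a
    bleaching trace first divides early and late trials by different
    effective baselines and degrades transient recovery.
    """
    out = np.empty_like(session.roi_traces)
    for i, raw in enumerate(session.roi_traces):
        det = detrend_quadratic(raw)
        offset = raw[
            _baseline_mask(raw.size, session.events, session.frame_rate_hz, pre_s)
        ].mean()
        out[i] = normalize_to_baseline(
            det, session.events, session.frame_rate_hz, pre_s, baseline_offset=offset
        )
    return out.mean(axis=0)


def parse_trials(
    trace: np.ndarray,
    events: list[tuple[float, float]],
    frame_rate_hz: float,
    pre_s: float = 5.0,
    post_s: float = 10.0,
) -> TrialMatrix:
    """Cut the normalized trace into onset-aligned trials.

    Trials whose window would be truncated by the session edges are dropped
    with a warning.  Each retained row is divided by its own pre-window mean
    so baseline bins average to 1 per trial by construction.
    """
    trace = np.asarray(trace, dtype=float)
    n_pre = int(round(pre_s * frame_rate_hz))
    n_post = int(round(post_s * frame_rate_hz))
    rows, onsets, durs = [], [], []
    dropped = 0
    for onset, offset in events:
        i0 = int(round(onset * frame_rate_hz))
        if i0 - n_pre < 0 or i0 + n_post > trace.size:
            dropped += 1
            continue
        row = trace[i0 - n_pre : i0 + n_post]
        base = row[:n_pre].mean()
        if base <= 0:
            raise NormalizationError(f"trial at {onset} s has non-positive baseline")
        rows.append(row / base)
        onsets.append(onset)
        durs.append(offset - onset)
    if dropped:
        warnings.warn(f"{dropped} trial(s) dropped: window truncated", stacklevel=2)
    if not rows:
        raise DataError("no complete trials in session")
    return TrialMatrix(
        data=np.array(rows),
        frame_rate_hz=frame_rate_hz,
        pre_s=pre_s,
        post_s=post_s,
        stim_dur_s=float(np.median(durs)),
        onsets_s=np.array(onsets),
    )


def binned_response(tm: TrialMatrix, bin_s: float = 1.0) -> pd.DataFrame:
    """Per-trial per-second means over the stimulation window.

    Returns a tidy frame (trial, bin_start_s, response); the companion
    :func:`binned_summary` provides the trial average with SEM.
    """
    if tm.stim_dur_s < bin_s:
        raise DataError(f"stim window {tm.stim_dur_s} s shorter than bin {bin_s} s")
    n_bins = int(round(tm.stim_dur_s / bin_s))
    per_bin = int(round(bin_s * tm.frame_rate_hz))
    i_on = int(round(tm.pre_s * tm.frame_rate_hz))
    records = []
    for trial in range(tm.n_trials):
        for b in range(n_bins):
            seg = tm.data[trial, i_on + b * per_bin : i_on + (b + 1) * per_bin]
            records.append(
                {"trial": trial + 1, "bin_start_s": b * bin_s, "response": seg.mean()}
            )
    return pd.DataFrame(records)


def binned_summary(tm: TrialMatrix, bin_s: float = 1.0) -> pd.DataFrame:
    """Trial-averaged binned response with SEM across trials."""
    df = binned_response(tm, bin_s)
    g = df.groupby("bin_start_s")["response"]
    return pd.DataFrame(
        {
            "bin_start_s": g.mean().index,
            "mean": g.mean().to_numpy(),
            "sem": (g.std(ddof=1) / np.sqrt(g.count())).to_numpy(),
        }
    )


def trial_means(tm: TrialMatrix) -> np.ndarray:
    """Per-trial mean normalized response over the stimulation window."""
    i_on = int(round(tm.pre_s * tm.frame_rate_hz))
    i_off = i_on + int(round(tm.stim_dur_s * tm.frame_rate_hz))
    return tm.data[:, i_on:i_off].mean(axis=1)


def session_average(tm: TrialMatrix) -> float:
    """Mean of per-trial stimulation-window means (trials are observations)."""
    if tm.n_trials < 1:
        raise DataError("session has no trials")
    return float(trial_means(tm).mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_session(
    traces_path: str | Path, events_path: str | Path, frame_rate_hz: float = 20.0
) -> PhotometrySession:
    """Read long-format traces (time_s or frame, roi_id, dff) + events CSV."""
    df = pd.read_csv(traces_path)
    if "dff" not in df.columns or "roi_id" not in df.columns:
        raise DataError(f"{traces_path}: expected columns roi_id, dff")
    if "time_s" in df.columns:
        order_col = "time_s"
    elif "frame" in df.columns:
        order_col = "frame"
    else:
        raise DataError(f"{traces_path}: need a time_s or frame column")
    wide = df.pivot_table(index=order_col, columns="roi_id", values="dff").sort_index()
    ev = pd.read_csv(events_path)
    events = [(float(r.onset_s), float(r.offset_s)) for r in ev.itertuples()]
    return PhotometrySession(
        frame_rate_hz=frame_rate_hz,
        roi_traces=wide.to_numpy().T,
        events=events,
        roi_ids=[str(c) for c in wide.columns],
    )


def save_session(session: PhotometrySession, traces_path: str | Path, events_path: str | Path) -> None:
    t = session.times_s
    frames = [
        pd.DataFrame({"time_s": t, "roi_id": rid, "dff": session.roi_traces[i]})
        for i, rid in enumerate(session.roi_ids)
    ]
    pd.concat(frames, ignore_index=True).to_csv(traces_path, index=False)
    pd.DataFrame(session.events, columns=["onset_s", "offset_s"]).to_csv(
        events_path, index=False
    )
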
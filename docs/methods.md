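# Methods

This note documents the models, conventions and numerical choices behind
`optoephys`, in the order the pipeline applies them.

## Signals and filtering

LFP recordings are two-channel (BLA, mPFC) microvolt series with a common
sampling rate taken from the data, never hard-coded. Band-pass filtering
uses a Chebyshev type II design, order 4 with 40 dB stopband attenuation,
applied forward–backward (`sosfiltfilt`) for zero phase. The session-level
default band is 1–250 Hz; optogenetic sessions use 3–300 Hz where the
sampling rate allows. For narrowband phase extraction (±1 Hz around a drive
frequency) the order drops to 2: a fourth-order Chebyshev II prescribed a
2 Hz-wide band at kilohertz rates is numerically fragile, and order 2 in a
zero-phase pass gives an effective fourth-order response.

## Time–frequency decomposition

Spectrograms are one-sided Hann-window STFT power densities (µV²/Hz).
Whole-session spectrograms use a 5 s window with 50 % overlap (0.2 Hz
resolution); optogenetic trials use 1 s bins with 50 % overlap so the
frequency grid is 1 Hz and the ±1 Hz quantification band contains exactly
three bins. Segments are not mean-detrended, so doubling the signal
amplitude exactly quadruples every bin. Line noise is handled in the
spectral domain: every frequency bin centred in 59–61 Hz is replaced, per
time bin, by the nearest bin outside the band; coarser grids with no bins
in the band pass through with a warning.

The Morse-wavelet spectrogram (generalized Morse wavelets, γ = 3, β = 20,
logarithmically spaced frequencies, computed by frequency-domain
multiplication) is strictly a visualization product; the power-ratio
quantification always uses the 1 s-bin STFT.

## Two-stage spectrogram outlier rejection

The screen operates on the mean power across frequencies, one value per
time bin.

* **Stage 1 (global):** bins strictly above mean + 4 SD are flagged. Their
  power columns are replaced by the per-frequency median over non-flagged
  bins, preserving spectral shape — the alternative reading (replacing only
  the screening series) would leave artifact power in downstream band
  averages.
* **Stage 2 (local):** a 5-min window is centred on every bin (truncated at
  the edges, step = one bin). A bin is flagged when it exceeds the window
  median + 5 × 1.4826 × MAD; the 1.4826 factor makes the MAD estimate an
  SD, and the test is one-sided high because power artifacts are positive.
  A zero-MAD (constant) window flags nothing, so silent segments are never
  wholesale rejected. Flagged bins are replaced by the most recent
  preceding clean bin (first-bin fallback: nearest following clean bin).
* The mask records the union of both stages; recordings shorter than one
  stage-2 window run stage 1 only, with a warning. All thresholds
  (4 SD, 5 × MAD, 5 min) are configurable with these defaults.

The screen presumes the sub-1 Hz band has been filtered out first: with a
raw 1/f background, the lowest bins dominate the mean-power series and its
upper tail, inflating false positives. The workflow therefore always
band-passes before cleaning.

## Evoked power

Per stimulation epoch, band power is the mean over all (time, frequency)
bins whose centres fall in the closed band [f − 1, f + 1] Hz and the
half-open, epoch-relative time window — stimulation (0, 120) s clipped at
the epoch offset, baseline (−30, 0) s. Epochs whose baseline window starts
before the data begin are skipped with a warning. The reported effect is
`ratio − 1` (no change = 0); the raw ratio is stored as well. Because both
windows share the recording's gain, the ratio is invariant to amplitude
scaling.

The inclusion screen groups repeats by (channel, frequency), computes the
population SD of their ratios and excludes repeats strictly beyond 2 SD
from the group mean. Note an arithmetic consequence: a single outlier among
*n* values can deviate at most (n − 1)/√n SD from the mean (1.15 SD at
n = 3, 1.79 at n = 5), so with three within-session repeats the 2 SD screen
can only bite when applied to larger groups (e.g. pooled across sessions or
animals); the grouping is therefore configurable and the deviation scores
are always exported. The screen uses the power ratio as the measurable
proxy for a "phase-locked response"; averaging uses included repeats only,
and a group with none is reported missing rather than zero.

## Phase coherence

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) of the narrowband-filtered channel. For a windowed average, 5 %
of the window's samples are dropped at each end to suppress filter and
window-edge transients; for whole-series averages the outer 5 % of the
recording is excluded instead.

PLV is the modulus, and iPLV the absolute imaginary part, of the
time-averaged unit phasor of the phase difference. Both are symmetric under
channel swap and invariant to a common phase rotation; iPLV ≤ PLV always.
The per-sample-rectified variant of iPLV is deliberately not used. Ratios
are formed per frequency as mean-over-repeats stimulation PLV divided by
mean-over-repeats baseline PLV (baseline reference = 1), with repeats
optionally restricted to those surviving the evoked-power screen. PLV has a
positive finite-sample bias (≈ √π/2√N for independent phases), so ratio
comparisons between windows of different lengths inherit a small
conservative bias toward the longer window; equal-length windows cancel it.
No directionality metric is computed — PLV/iPLV are symmetric by
construction.

## Photometry

The processing order is fixed: quadratic detrend → baseline normalization
→ trial parsing. Detrending fits one second-degree polynomial to the whole
trace (Chebyshev-scaled time axis for conditioning) and subtracts it;
normalizing first would divide early and late trials by different effective
baselines, which a regression test guards against. Because the detrended
trace is near zero-mean, the normalization adds back the pre-stimulation
mean of the raw trace before dividing, so baseline maps to 1:
`normalized = (detrended + baseline_raw) / baseline_raw`. The per-trial
baseline window is the 5 s before onset; trials are cut 5 s pre / 10 s post
onset, and each trial row is renormalized by its own pre-window mean so
baseline averages to exactly 1 per trial. Binning covers the 5 s
stimulation window in 1 s bins; the session average is the mean of
per-trial stimulation-window means, with per-trial values retained because
dopamine depletion makes trials serially dependent. Multiple ROIs are
averaged with equal weights after normalization.

## Behavior

Zone membership is radial: the nose is in a cup's interaction zone when its
Euclidean distance to the cup centre is ≤ cup radius (4 cm) + margin
(3 cm) = 7 cm. Occupancy integrates sample-and-hold: each sample represents
the half-open span to the next sample (the last sample inherits the final
step). There is no entry debounce — single-sample entries count — and
closed-loop stimulation epochs are exactly the stimulation-side zone
intervals, so total stimulation time equals T_S identically. Chambers are
the three equal x-thirds of the 71 × 30 cm arena; chamber times sum to the
session duration within one sample period. Positions more than 1 cm outside
the arena are clipped with a logged count.

Scores follow the ×100 formulas exactly: PS = 100·T_S/(T_S + T_NS) and
NS = 100·PS_T/PS_H, so equal time gives PS = 50 and no change gives
NS = 100. (Figure-caption phrasings that place "equivalence" at 1 reflect a
÷100 display scale; the formulas govern here, and dividing for display is
left to the caller.) Undefined cases — no zone time at all, or PS_H = 0 —
are reported as missing (NaN), never as zero.

## Synthetic data

The generators are pure functions of their configuration, seed included.

* **LFP:** background is 1/f^α noise (α = 1 default) synthesized by
  spectral shaping of white Gaussian noise, normalized to a configurable
  RMS (50 µV default) per channel. The default schedule is the full
  recording design — 5/10/20/40 Hz, three pseudorandomized repeats each,
  120 s epochs with 60 s gaps at 1 kHz. The stimulation-locked component is
  a sinusoid (a 5 ms rectangular pulse train is available as an option);
  channel 2's copy is phase-shifted by the configured lag. The optional
  zero-lag component is one extra 1/f trace added identically to both
  channels — a volume-conduction stand-in that drives PLV up while leaving
  iPLV near zero. Artifacts are 0.5 s broadband noise bursts under a
  half-sine envelope; a smooth half-sine alone concentrates its energy near
  1 Hz and is largely removed by the band-pass, whereas movement/EMG-like
  artifacts are broadband, which is what the outlier screen must catch.
* **Photometry:** trace = quadratic bleaching trend + per-trial transients
  + Gaussian noise; the transient kernel is a peak-normalized difference of
  exponentials (rise 0.2 s, decay 1.5 s) with an optional per-trial
  multiplicative amplitude decay emulating depletion. The default protocol
  is 15 trials of 5 s every 30 s at 20 fps, first onset at 30 s. The true
  trend, transient train and kernel area are stored as ground truth.
* **Trajectory:** a reflected random walk (step SD 2 cm at 25 Hz) with two
  knobs: zone stickiness (step damping inside a zone, producing dwell
  episodes) and side bias (a constant drift toward — or, below 0.5, away
  from — the stimulation-side cup). The drift saturates quickly: biases
  moderately away from 0.5 produce strong occupancy asymmetries over a
  10 min session, so the parameter orders scenarios rather than calibrating
  effect sizes. Ground-truth zone times are recorded at generation.

What the generators do **not** emulate: non-stationary or oscillatory
neural background (the 1/f noise has no endogenous rhythms or state
changes), sensor kinetics beyond a fixed kernel, gain differences across
photometry sessions, tracking noise or body-pose ambiguity, and any
coupling between modalities. Passing tests therefore demonstrate that the
quantification chain recovers known structure under the stated noise
models — not that it is robust to every failure mode of in-vivo data.

## Problem sizes in tests and validation

The generator defaults are the full recording design; the test suite and
`scripts/acceptance.py` run scaled sessions — 250 Hz sampling, 10 s epochs
with 6 s baselines and epoch-relative windows (0, 10)/(−6, 0) s, 620 s
artifact sessions, 240 s behavior sessions — chosen so the complete
validation (Monte-Carlo loops of 50–100 seeds included) finishes in a
couple of minutes while every window still contains well over ten cycles of
the lowest drive frequency. Detection margins at these sizes are wide
(drive amplitude twice the noise RMS elevates three-bin band power by an
order of magnitude), so the scaling does not sit near any decision
boundary.

## File formats

Delimited-text recordings (`time_s` + one column per channel), protocol /
photometry / trajectory CSVs with the documented headers, arena geometry as
YAML, spectrograms as HDF5 (`power`, `times_s`, `freqs_hz`, `mask` +
parameter attributes). EDF export is a built-in 16-bit encoder (1 s data
records, physical unit µV, trailing partial seconds dropped); EDF import
uses mne, and the round trip is tested against it at 16-bit quantization
tolerance. Result tables carry full parameter provenance in a JSON
manifest; identical configs produce byte-identical outputs.

## Known limitations

* The ±2 SD inclusion screen is mathematically inert for n = 3 repeat
  groups (see above); it is implemented as specified and becomes active for
  pooled groups.
* Stage-2 outlier replacement (forward fill) is order-dependent by design;
  re-running the cleaner can in principle flag bins adjacent to replaced
  runs, though the stage-1 criterion is idempotent in practice.
* PLV/iPLV ratios compare windows of different lengths (120 s vs 30 s at
  defaults) and inherit PLV's small-sample bias toward the shorter window's
  baseline; conclusions should rest on comparisons sharing a window
  geometry, as all shipped analyses do.
* The EDF encoder targets the plain EDF profile (no annotations, integer
  sampling rates).
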
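"""Shared settings for the analysis drivers.

All drivers operate on a scaled-down synthetic session (250 Hz sampling,
10 s stimulation epochs with 6 s baselines) so the full analysis chain runs
in seconds; the generator defaults reproduce the full recording design
(1 kHz, 120 s epochs, 30 s baselines) when run without overrides.
"""

from pathlib import Path

import optoephys as oe

SEED = 1
DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "synthetic"
RESULTS_DIR = Path(__file__).resolve().parent.parent / "results"

STIM_WINDOW_S = (0.0, 10.0)
BASE_WINDOW_S = (-6.0, 0.0)
BAND_HZ = (1.0, 100.0)


def lfp_config(seed=SEED, **overrides):
    kwargs = dict(
        seed=seed,
        fs_hz=250.0,
        noise_amp=15.0,
        stim_amp=30.0,
        phase_lag_rad=0.4,
        line_noise_amp=5.0,
        stim_schedule=oe.pseudorandom_schedule(
            (5.0, 10.0, 20.0, 40.0), n_repeats=3, stim_dur_s=10.0,
            gap_s=6.0, lead_in_s=6.0, seed=seed,
        ),
    )
    kwargs.update(overrides)
    return oe.SyntheticLFPConfig(**kwargs)
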
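import numpy as np
import pytest

from optoephys import (
    LFPRecording,
    SyntheticLFPConfig,
    pseudorandom_schedule,
)


def short_lfp_config(seed: int = 0, **overrides) -> SyntheticLFPConfig:
    """Scaled-down dual-site LFP session: 4 frequencies x 3 repeats of 10 s
    epochs with 6 s baselines at 250 Hz; analysis windows are passed
    explicitly by the tests that use it."""
    kwargs = dict(
        seed=seed,
        fs_hz=250.0,
        noise_amp=15.0,
        stim_amp=30.0,
        stim_schedule=pseudorandom_schedule(
            (5.0, 10.0, 20.0, 40.0),
            n_repeats=3,
            stim_dur_s=10.0,
            gap_s=6.0,
            lead_in_s=6.0,
            seed=seed,
        ),
    )
    kwargs.update(overrides)
    return SyntheticLFPConfig(**kwargs)


SHORT_WINDOWS = dict(stim_window_s=(0.0, 10.0), base_window_s=(-6.0, 0.0))


@pytest.fixture
def tone_pair():
    """Noiseless 20 Hz sinusoid pair with a pi/4 lag on the second channel."""
    fs = 500.0
    t = np.arange(0, 60, 1 / fs)
    x = np.cos(2 * np.pi * 20 * t)
    y = np.cos(2 * np.pi * 20 * t - np.pi / 4)
    return LFPRecording(["BLA", "mPFC"], fs, np.vstack([x, y]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
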
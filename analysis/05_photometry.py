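"""Dopamine-sensor trial analysis of the synthetic GRAB-DA-style session.

Detrends the ROI trace (quadratic photobleaching), normalizes it to the
pre-stimulation baseline, parses the 15 trials, bins the 5 s stimulation
window per second, and reports per-trial and session-average responses.
"""

import runpy
from pathlib import Path

import numpy as np
import pandas as pd

import optoephys as oe
from optoephys.photometry import load_session

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))
DATA_DIR, RESULTS_DIR = cfg["DATA_DIR"], cfg["RESULTS_DIR"]
RESULTS_DIR.mkdir(parents=True, exist_ok=True)

session = load_session(DATA_DIR / "dff.csv", DATA_DIR / "stim_events.csv", 20.0)
norm = oe.preprocess_session(session, pre_s=5.0)
tm = oe.parse_trials(norm, session.events, session.frame_rate_hz,
                     pre_s=5.0, post_s=10.0)

oe.binned_response(tm, 1.0).to_csv(RESULTS_DIR / "photometry_trial_bins.csv",
                                   index=False)
summary = oe.binned_summary(tm, 1.0)
summary.to_csv(RESULTS_DIR / "photometry_binned_summary.csv", index=False)
means = oe.trial_means(tm)
pd.DataFrame({"trial": np.arange(1, tm.n_trials + 1), "mean_response": means}).to_csv(
    RESULTS_DIR / "photometry_trial_means.csv", index=False
)

print(summary.to_string(index=False))
print(f"\n{tm.n_trials} trials; session-average normalized response "
      f"{oe.session_average(tm):.3f} (baseline = 1). Trial means drift from "
      f"{means[0]:.3f} to {means[-1]:.3f}: the generator's mild per-trial "
      "amplitude decay (depletion emulation) is visible, which is why trials "
      "are kept as the observational unit.")
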
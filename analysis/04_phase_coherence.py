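"""BLA->mPFC phase coherence (PLV and iPLV) around each drive frequency.

Computes narrowband Hilbert phases per drive frequency, PLV/iPLV in the
stimulation and baseline windows of every repeat, their stimulation-to-
baseline ratios, and the phase-difference histogram at 40 Hz.
"""

import runpy
from pathlib import Path

import optoephys as oe
from optoephys.coherence import results_to_frame

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))
DATA_DIR, RESULTS_DIR = cfg["DATA_DIR"], cfg["RESULTS_DIR"]
RESULTS_DIR.mkdir(parents=True, exist_ok=True)

rec = oe.load_recording(DATA_DIR / "lfp.csv")
protocol = oe.StimProtocol.from_csv(DATA_DIR / "stim_protocol.csv")

results = oe.coherence_ratio(
    rec, protocol,
    stim_window_s=cfg["STIM_WINDOW_S"], base_window_s=cfg["BASE_WINDOW_S"],
)
df = results_to_frame(results)
df.to_csv(RESULTS_DIR / "coherence.csv", index=False)
print(df.to_string(index=False))

r40 = next(r for r in results if r.freq_hz == 40.0)
oe.phase_histogram(r40, n_bins=36).to_csv(
    RESULTS_DIR / "phase_histogram_40hz.csv", index=False
)
print(f"\n40 Hz: PLV ratio {r40.plv_ratio:.2f}, iPLV ratio {r40.iplv_ratio:.2f} "
      "(the injected 0.4 rad lag makes stimulation-locked coherence visible "
      "to iPLV as well as PLV).")
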
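"""Stimulation-evoked power ratios per drive frequency.

Quantifies band power within +/-1 Hz of each drive frequency during
stimulation versus the pre-onset baseline (1 s STFT bins), applies the
+/-2 SD inclusion screen, averages repeats, and tabulates ratios by
presentation order.
"""

import runpy
from pathlib import Path

import optoephys as oe
from optoephys.evoked import results_to_frame

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))
DATA_DIR, RESULTS_DIR = cfg["DATA_DIR"], cfg["RESULTS_DIR"]
RESULTS_DIR.mkdir(parents=True, exist_ok=True)

rec = oe.load_recording(DATA_DIR / "lfp.csv")
protocol = oe.StimProtocol.from_csv(DATA_DIR / "stim_protocol.csv")

all_results = []
for ch in rec.channel_labels:
    spec = oe.compute_stft(rec, ch, window_s=1.0, overlap_frac=0.5)
    spec = oe.remove_line_noise(spec, (59.0, 61.0))
    res = oe.power_ratio(
        spec, protocol,
        stim_window_s=cfg["STIM_WINDOW_S"], base_window_s=cfg["BASE_WINDOW_S"],
    )
    oe.inclusion_filter(res, k=2.0)
    all_results.extend(res)

results_to_frame(all_results).to_csv(RESULTS_DIR / "power_ratio.csv", index=False)
means = oe.average_repeats(all_results)
means.to_csv(RESULTS_DIR / "power_ratio_mean.csv", index=False)
order = oe.presentation_order_effect(all_results)
order.to_csv(RESULTS_DIR / "presentation_order.csv", index=False)

print(means.to_string(index=False))
print("Every drive frequency shows mean ratio-1 > 0 (stimulation-locked "
      "power above baseline) on both channels:",
      bool((means["mean_ratio_minus_1"] > 0).all()))
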
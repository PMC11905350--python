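"""Generate the synthetic datasets every later driver consumes.

Writes a dual-site LFP recording with its stimulation protocol, a
dopamine-sensor session, and four 3CST trajectories (habituation/testing x
Toy-Toy/Toy-Female) under data/synthetic/.
"""

import runpy
from pathlib import Path

import optoephys as oe
from optoephys.photometry import save_session
from optoephys.synthetic import save_trajectory_with_arena, write_lfp_text

cfg_mod = runpy.run_path(Path(__file__).with_name("00_config.py"))
SEED, DATA_DIR = cfg_mod["SEED"], cfg_mod["DATA_DIR"]

DATA_DIR.mkdir(parents=True, exist_ok=True)

# LFP: 4 drive frequencies x 3 pseudorandomized repeats, pi/4-ish lag
rec, protocol = oe.generate_lfp_pair(cfg_mod["lfp_config"]())
write_lfp_text(rec, DATA_DIR / "lfp.csv")
protocol.to_csv(DATA_DIR / "stim_protocol.csv")
print(f"LFP: {rec.duration_s:.0f} s, {len(protocol)} stimulation epochs "
      f"-> {DATA_DIR / 'lfp.csv'}")

# photometry: 15 x 5 s trains every 30 s, mild depletion across trials
pcfg = oe.SyntheticPhotometryConfig(seed=SEED, transient_amp=0.5,
                                    amp_decay=0.97, noise_sd=0.05)
session = oe.generate_photometry(pcfg)
save_session(session, DATA_DIR / "dff.csv", DATA_DIR / "stim_events.csv")
print(f"photometry: {session.n_frames} frames, {len(session.events)} trials "
      f"-> {DATA_DIR / 'dff.csv'}")

# behavior: neutral habituation, stimulation-avoidant testing trials
biases = {
    ("ToyToy", "habituation"): 0.5,
    ("ToyToy", "testing"): 0.35,
    ("ToyFemale", "habituation"): 0.6,
    ("ToyFemale", "testing"): 0.4,
}
for i, ((stype, ttype), bias) in enumerate(biases.items()):
    bcfg = oe.SyntheticBehaviorConfig(
        seed=SEED * 100 + i, duration_s=600.0, side_bias=bias, stim_side="left"
    )
    s = oe.generate_trajectory(bcfg)
    name = f"trajectory_{stype}_{ttype}"
    save_trajectory_with_arena(
        s, DATA_DIR / f"{name}.csv", DATA_DIR / "arena.yaml"
    )
    tz = s.ground_truth["time_in_zone"]
    print(f"behavior {stype}/{ttype} (bias {bias}): ground-truth zone time "
          f"L={tz['left']:.0f}s R={tz['right']:.0f}s")
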
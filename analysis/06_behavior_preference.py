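"""Closed-loop 3CST scoring of the synthetic trajectories.

Computes interaction-zone occupancy and chamber times for the four trials,
derives the closed-loop stimulation epochs, and scores PS per trial and NS
per session type.
"""

import runpy
from pathlib import Path

import pandas as pd

import optoephys as oe
from optoephys.behavior import load_trajectory
from optoephys.synthetic import load_arena_yaml

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))
DATA_DIR, RESULTS_DIR = cfg["DATA_DIR"], cfg["RESULTS_DIR"]
RESULTS_DIR.mkdir(parents=True, exist_ok=True)

geometry = load_arena_yaml(DATA_DIR / "arena.yaml")
trial_rows, ps = [], {}
for stype in ("ToyToy", "ToyFemale"):
    for ttype in ("habituation", "testing"):
        s = load_trajectory(
            DATA_DIR / f"trajectory_{stype}_{ttype}.csv",
            stim_side="left" if ttype == "testing" else None,
            trial_type=ttype, session_type=stype,
        )
        occ = oe.zone_occupancy(s, geometry)
        ps[(stype, ttype)] = oe.preference_score(
            occ.seconds["left"], occ.seconds["right"]
        )
        stim_time = sum(
            b - a for a, b in oe.closed_loop_epochs(occ, "left")
        ) if ttype == "testing" else 0.0
        ct = oe.chamber_times(s, geometry)
        trial_rows.append(
            {"session": stype, "trial": ttype,
             "t_s": occ.seconds["left"], "t_ns": occ.seconds["right"],
             "ps": ps[(stype, ttype)], "stim_time_s": stim_time,
             **{f"chamber_{k}_s": v for k, v in ct.items()}}
        )

trials = pd.DataFrame(trial_rows)
trials.to_csv(RESULTS_DIR / "behavior_trials.csv", index=False)
scores = pd.DataFrame(
    [
        {"session": stype,
         "ps_habituation": ps[(stype, "habituation")],
         "ps_testing": ps[(stype, "testing")],
         "ns": oe.normalized_preference(ps[(stype, "testing")],
                                        ps[(stype, "habituation")])}
        for stype in ("ToyToy", "ToyFemale")
    ]
)
scores.to_csv(RESULTS_DIR / "behavior_scores.csv", index=False)

print(trials.to_string(index=False))
print()
print(scores.to_string(index=False))
print("\nBoth session types were generated stimulation-avoidant during "
      "testing, and both NS values fall below 100 accordingly; closed-loop "
      "stimulation time equals T_S by construction of the trigger logic.")
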
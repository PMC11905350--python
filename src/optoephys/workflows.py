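"""End-to-end workflows tying the pipeline stages together.

Each workflow reads (or synthesizes) its inputs, runs every stage with the
configured parameters, persists result tables under ``out_dir`` and writes
a manifest recording the full parameter provenance.  Two runs with the same
config and inputs produce byte-identical tables.  A failing stage aborts
the run with a stage-named error and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    ArenaGeometry,
    chamber_times,
    closed_loop_epochs,
    load_trajectory,
    normalized_preference,
    preference_score,
    session_protocol_check,
    zone_occupancy,
)
from .coherence import coherence_ratio
from .coherence import results_to_frame as coherence_frame
from .errors import ConfigError, DataError, OptoEphysError
from .evoked import (
    average_repeats,
    inclusion_filter,
    power_ratio,
    presentation_order_effect,
)
from .evoked import results_to_frame as evoked_frame
from .lfp import (
    bandpass,
    compute_stft,
    detect_outliers,
    load_recording,
    remove_line_noise,
    save_spectrogram_h5,
)
from .photometry import (
    binned_response,
    binned_summary,
    load_session,
    parse_trials,
    preprocess_session,
    session_average,
    trial_means,
)
from .protocol import StimProtocol
from .synthetic import (
    SyntheticBehaviorConfig,
    SyntheticLFPConfig,
    SyntheticPhotometryConfig,
    generate_lfp_pair,
    generate_photometry,
    generate_trajectory,
    load_arena_yaml,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All analysis parameters with the study's stated values as defaults."""

    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    # inputs (None -> synthesize from the seed)
    lfp_path: str | None = None
    protocol_path: str | None = None
    photometry_traces_path: str | None = None
    photometry_events_path: str | None = None
    trajectory_paths: dict = field(default_factory=dict)  # trial name -> path
    arena_path: str | None = None
    # LFP preprocessing
    band_hz: tuple[float, float] = (1.0, 250.0)
    window_s: float = 5.0
    overlap_frac: float = 0.5
    opto_window_s: float = 1.0
    line_band_hz: tuple[float, float] = (59.0, 61.0)
    clean: bool = True
    global_k: float = 4.0
    mad_k: float = 5.0
    window_min: float = 5.0
    # evoked power / coherence
    stim_window_s: tuple[float, float] = (0.0, 120.0)
    base_window_s: tuple[float, float] = (-30.0, 0.0)
    half_width_hz: float = 1.0
    inclusion_sd: float = 2.0
    # photometry
    frame_rate_hz: float = 20.0
    pre_s: float = 5.0
    post_s: float = 10.0
    bin_s: float = 1.0
    # synthetic overrides (dicts passed to the generator configs)
    synth_lfp: dict = field(default_factory=dict)
    synth_photometry: dict = field(default_factory=dict)
    synth_behavior: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band_hz", "line_band_hz", "stim_window_s", "base_window_s"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class _Bundle:
    """Tracks written files so a failed stage can remove partial outputs."""

    def __init__(self, out_dir: str | Path):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.tables: dict[str, pd.DataFrame] = {}

    def write_csv(self, name: str, df: pd.DataFrame) -> Path:
        path = self.out_dir / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        self.files.append(path)
        self.tables[name] = df
        return path

    def write_manifest(self, config: RunConfig, workflow: str, extra: dict | None = None):
        manifest = {
            "workflow": workflow,
            "version": __version__,
            "parameters": config.to_dict(),
        }
        if extra:
            manifest.update(extra)
        path = self.out_dir / f"{workflow}_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        self.files.append(path)

    def cleanup(self) -> None:
        for p in self.files:
            p.unlink(missing_ok=True)


def _stage(bundle: _Bundle, name: str):
    """Context manager: on failure, remove partial outputs and re-raise."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                bundle.cleanup()
                raise OptoEphysError(f"stage '{name}' failed: {exc}") from exc

    return _Ctx()


# ---------------------------------------------------------------------------
# LFP workflow
# ---------------------------------------------------------------------------

def run_lfp_workflow(config: RunConfig) -> _Bundle:
    """Spectrograms + cleaning + evoked power + coherence, persisted."""
    bundle = _Bundle(config.out_dir)

    with _stage(bundle, "load"):
        if config.lfp_path is not None:
            rec = load_recording(config.lfp_path)
            if config.protocol_path is None:
                raise DataError("protocol_path required when lfp_path is given")
            protocol = StimProtocol.from_csv(config.protocol_path)
        else:
            synth = SyntheticLFPConfig(seed=config.seed, **config.synth_lfp)
            rec, protocol = generate_lfp_pair(synth)

    with _stage(bundle, "bandpass"):
        rec_f = bandpass(rec, *config.band_hz)

    with _stage(bundle, "spectrogram"):
        for ch in rec_f.channel_labels:
            spec = compute_stft(rec_f, ch, config.window_s, config.overlap_frac)
            spec = remove_line_noise(spec, config.line_band_hz)
            if config.clean:
                spec = detect_outliers(
                    spec, config.global_k, config.mad_k, config.window_min
                )
                logger.info(
                    "channel %s: %d/%d bins flagged",
                    ch, int(spec.outlier_mask.sum()), spec.outlier_mask.size,
                )
            path = bundle.out_dir / f"spectrogram_{ch}.h5"
            save_spectrogram_h5(spec, path)
            bundle.files.append(path)

    with _stage(bundle, "evoked_power"):
        all_results = []
        for ch in rec_f.channel_labels:
            opto = compute_stft(rec_f, ch, config.opto_window_s, config.overlap_frac)
            opto = remove_line_noise(opto, config.line_band_hz)
            res = power_ratio(
                opto, protocol, config.stim_window_s, config.base_window_s,
                config.half_width_hz,
            )
            inclusion_filter(res, config.inclusion_sd)
            all_results.extend(res)
        bundle.write_csv("power_ratio.csv", evoked_frame(all_results))
        bundle.write_csv("power_ratio_mean.csv", average_repeats(all_results))
        bundle.write_csv(
            "presentation_order.csv", presentation_order_effect(all_results)
        )

    with _stage(bundle, "coherence"):
        included = {
            (r.freq_hz, r.repeat_idx)
            for r in all_results
            if r.channel_label == rec_f.channel_labels[0] and r.included
        }
        coh = coherence_ratio(
            rec_f, protocol,
            channels=(rec_f.channel_labels[0], rec_f.channel_labels[1]),
            stim_window_s=config.stim_window_s,
            base_window_s=config.base_window_s,
            half_width_hz=config.half_width_hz,
            included=included,
        )
        bundle.write_csv("coherence.csv", coherence_frame(coh))

    bundle.write_manifest(config, "lfp", {"n_epochs": len(protocol)})
    return bundle


# ---------------------------------------------------------------------------
# photometry workflow
# ---------------------------------------------------------------------------

def run_photometry_workflow(config: RunConfig) -> _Bundle:
    """Detrend + normalize + trial parsing + per-second binning + summary."""
    bundle = _Bundle(config.out_dir)

    with _stage(bundle, "load"):
        if config.photometry_traces_path is not None:
            session = load_session(
                config.photometry_traces_path,
                config.photometry_events_path,
                config.frame_rate_hz,
            )
        else:
            synth = SyntheticPhotometryConfig(seed=config.seed, **config.synth_photometry)
            session = generate_photometry(synth)
        if not session.events:
            raise DataError("session has no stimulation events")

    with _stage(bundle, "preprocess"):
        norm = preprocess_session(session, config.pre_s)

    with _stage(bundle, "trials"):
        tm = parse_trials(
            norm, session.events, session.frame_rate_hz, config.pre_s, config.post_s
        )
        bundle.write_csv("trial_bins.csv", binned_response(tm, config.bin_s))
        bundle.write_csv("trial_bins_summary.csv", binned_summary(tm, config.bin_s))
        means = trial_means(tm)
        bundle.write_csv(
            "trial_means.csv",
            pd.DataFrame({"trial": np.arange(1, tm.n_trials + 1), "mean_response": means}),
        )
        summary = {
            "session_average": session_average(tm),
            "n_trials": tm.n_trials,
            "stim_dur_s": tm.stim_dur_s,
        }
        path = bundle.out_dir / "photometry_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        bundle.files.append(path)

    bundle.write_manifest(config, "photometry")
    return bundle


# ---------------------------------------------------------------------------
# behavior workflow
# ---------------------------------------------------------------------------

def run_behavior_workflow(config: RunConfig) -> _Bundle:
    """Zone occupancy, closed-loop epochs, PS/NS and chamber times.

    Without input trajectories, a full counterbalanced 4-trial session
    (habituation/testing x ToyToy/ToyFemale) is synthesized from the seed.
    """
    bundle = _Bundle(config.out_dir)

    with _stage(bundle, "load"):
        geometry = (
            load_arena_yaml(config.arena_path) if config.arena_path else ArenaGeometry()
        )
        sessions: dict[tuple[str, str], object] = {}
        if config.trajectory_paths:
            for key, item in config.trajectory_paths.items():
                stype, ttype = key.split("/")
                sessions[(stype, ttype)] = load_trajectory(
                    item["path"],
                    stim_side=item.get("stim_side"),
                    trial_type=ttype,
                    session_type=stype,
                )
        else:
            base = SyntheticBehaviorConfig(seed=config.seed, **config.synth_behavior)
            for i, (stype, ttype) in enumerate(
                [("ToyToy", "habituation"), ("ToyToy", "testing"),
                 ("ToyFemale", "habituation"), ("ToyFemale", "testing")]
            ):
                cfg = dataclasses.replace(base, seed=base.seed * 10 + i)
                s = generate_trajectory(cfg)
                s.trial_type = ttype
                s.session_type = stype
                s.stim_side = cfg.stim_side if ttype == "testing" else None
                sessions[(stype, ttype)] = s

    with _stage(bundle, "protocol_check"):
        rows = [
            {
                "animal": "synthetic" if not config.trajectory_paths else "input",
                "session": stype,
                "trial": ttype,
                "stim": "On" if s.stim_side else "Off",
                "stim_side": s.stim_side or "-",
            }
            for (stype, ttype), s in sessions.items()
        ]
        report = session_protocol_check(rows)
        path = bundle.out_dir / "protocol_check.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        bundle.files.append(path)

    with _stage(bundle, "scoring"):
        trial_rows, score_rows = [], []
        ps: dict[tuple[str, str], float] = {}
        for (stype, ttype), s in sorted(sessions.items()):
            occ = zone_occupancy(s, geometry)
            if s.stim_side:
                side = s.stim_side
            else:
                # habituation: score the side assigned for the testing trial
                paired = sessions.get((stype, "testing"))
                side = getattr(paired, "stim_side", None) or "left"
            t_s = occ.seconds[side]
            t_ns = occ.seconds["right" if side == "left" else "left"]
            ps[(stype, ttype)] = preference_score(t_s, t_ns)
            ch = chamber_times(s, geometry)
            stim_total = (
                sum(b - a for a, b in closed_loop_epochs(occ, s.stim_side))
                if s.stim_side
                else 0.0
            )
            trial_rows.append(
                {
                    "session": stype,
                    "trial": ttype,
                    "stim_side": s.stim_side or "-",
                    "t_s": t_s,
                    "t_ns": t_ns,
                    "ps": ps[(stype, ttype)],
                    "stim_time_s": stim_total,
                    "chamber_left_s": ch["left"],
                    "chamber_center_s": ch["center"],
                    "chamber_right_s": ch["right"],
                }
            )
        for stype in ("ToyToy", "ToyFemale"):
            if (stype, "testing") in ps and (stype, "habituation") in ps:
                score_rows.append(
                    {
                        "session": stype,
                        "ps_habituation": ps[(stype, "habituation")],
                        "ps_testing": ps[(stype, "testing")],
                        "ns": normalized_preference(
                            ps[(stype, "testing")], ps[(stype, "habituation")]
                        ),
                    }
                )
        bundle.write_csv("behavior_trials.csv", pd.DataFrame(trial_rows))
        bundle.write_csv("behavior_scores.csv", pd.DataFrame(score_rows))

    bundle.write_manifest(config, "behavior")
    return bundle


def run_all(config: RunConfig) -> list[_Bundle]:
    """Run the LFP, photometry and behavior workflows with one config."""
    return [
        run_lfp_workflow(config),
        run_photometry_workflow(config),
        run_behavior_workflow(config),
    ]
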
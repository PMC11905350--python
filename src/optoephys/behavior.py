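"""Three-chamber social interaction task (3CST) scoring.

A 71 x 30 cm arena is split into three equal chambers; an inverted wire cup
(radius 4 cm) sits in the centre of each side chamber and the interaction
zone extends 3 cm beyond the cup (zone radius 7 cm).  During testing trials
a closed loop delivers photostimulation for exactly as long as the nose is
inside the stimulation-side zone.  Preference is scored from cumulative
nose-in-zone time:

    PS = 100 * T_S / (T_S + T_NS)          (stimulation-side share, percent)
    NS = 100 * PS_testing / PS_habituation (change relative to habituation)

PS = 50 means equal time at both cups; NS = 100 means stimulation left the
preference unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

SIDES = ("left", "right")


@dataclass
class ArenaGeometry:
    """Three-chamber arena with side cups and interaction-zone margin (cm)."""

    width_cm: float = 71.0
    depth_cm: float = 30.0
    cup_radius_cm: float = 4.0
    zone_margin_cm: float = 3.0
    cup_left_cm: tuple[float, float] | None = None
    cup_right_cm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        third = self.width_cm / 3.0
        if self.cup_left_cm is None:
            self.cup_left_cm = (third / 2.0, self.depth_cm / 2.0)
        if self.cup_right_cm is None:
            self.cup_right_cm = (self.width_cm - third / 2.0, self.depth_cm / 2.0)
        if self.zone_margin_cm <= 0:
            raise ConfigError(f"zone_margin_cm must be > 0, got {self.zone_margin_cm}")
        if not (0 < self.cup_left_cm[0] < third):
            raise ConfigError(f"cup_left_cm {self.cup_left_cm} outside left chamber")
        if not (2 * third < self.cup_right_cm[0] < self.width_cm):
            raise ConfigError(f"cup_right_cm {self.cup_right_cm} outside right chamber")
        for name, cup in (("cup_left_cm", self.cup_left_cm), ("cup_right_cm", self.cup_right_cm)):
            if not (0 < cup[1] < self.depth_cm):
                raise ConfigError(f"{name} {cup} outside arena depth")

    @property
    def zone_radius_cm(self) -> float:
        return self.cup_radius_cm + self.zone_margin_cm

    @property
    def chamber_edges_cm(self) -> tuple[float, float]:
        return (self.width_cm / 3.0, 2.0 * self.width_cm / 3.0)

    def cup_center(self, side: str) -> tuple[float, float]:
        if side == "left":
            return self.cup_left_cm
        if side == "right":
            return self.cup_right_cm
        raise ConfigError(f"side must be 'left' or 'right', got {side!r}")


@dataclass
class BehaviorSession:
    """Nose trajectory with trial metadata and (synthetic-only) ground truth."""

    time_s: np.ndarray
    nose_x_cm: np.ndarray
    nose_y_cm: np.ndarray
    stim_side: str | None = None
    trial_type: str = "habituation"  # habituation | testing
    session_type: str = "ToyToy"  # ToyToy | ToyFemale
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.nose_x_cm = np.asarray(self.nose_x_cm, dtype=float)
        self.nose_y_cm = np.asarray(self.nose_y_cm, dtype=float)
        if not (self.time_s.size == self.nose_x_cm.size == self.nose_y_cm.size):
            raise DataError("time and position arrays must have equal length")
        if self.time_s.size == 0:
            raise DataError("empty trajectory")
        if np.any(np.diff(self.time_s) <= 0):
            raise DataError("time stamps must be strictly increasing")
        if self.stim_side is not None and self.stim_side not in SIDES:
            raise DataError(f"stim_side must be one of {SIDES}, got {self.stim_side!r}")


@dataclass
class ZoneOccupancy:
    """Half-open in-zone intervals and cumulative seconds per side."""

    intervals: dict[str, list[tuple[float, float]]]
    seconds: dict[str, float]


@dataclass
class PreferenceResult:
    ps_t: float
    ps_h: float
    ns: float = field(init=False)

    def __post_init__(self) -> None:
        self.ns = normalized_preference(self.ps_t, self.ps_h)


def _sample_spans(time_s: np.ndarray) -> np.ndarray:
    """Sample-and-hold span of each sample (last sample inherits the final step)."""
    if time_s.size == 1:
        return np.array([0.0])
    dt = np.diff(time_s)
    return np.append(dt, dt[-1])


def _clipped_positions(
    session: BehaviorSession, geometry: ArenaGeometry
) -> tuple[np.ndarray, np.ndarray]:
    x, y = session.nose_x_cm, session.nose_y_cm
    out = (
        (x < -1.0) | (x > geometry.width_cm + 1.0)
        | (y < -1.0) | (y > geometry.depth_cm + 1.0)
    )
    if out.any():
        logger.warning(
            "%d sample(s) outside the arena by > 1 cm; clipped", int(out.sum())
        )
    return (
        np.clip(x, 0.0, geometry.width_cm),
        np.clip(y, 0.0, geometry.depth_cm),
    )


def zone_occupancy(session: BehaviorSession, geometry: ArenaGeometry) -> ZoneOccupancy:
    """In-zone intervals and cumulative time per side.

    The nose is in a zone when its Euclidean distance to that cup's centre
    is at most cup radius + margin (7 cm at defaults).  Each sample stands
    for the half-open span up to the next sample.
    """
    x, y = _clipped_positions(session, geometry)
    spans = _sample_spans(session.time_s)
    intervals: dict[str, list[tuple[float, float]]] = {}
    seconds: dict[str, float] = {}
    for side in SIDES:
        cx, cy = geometry.cup_center(side)
        inside = np.hypot(x - cx, y - cy) <= geometry.zone_radius_cm
        seconds[side] = float(spans[inside].sum())
        ivals: list[tuple[float, float]] = []
        i = 0
        n = inside.size
        while i < n:
            if inside[i]:
                j = i
                while j + 1 < n and inside[j + 1]:
                    j += 1
                end = session.time_s[j] + spans[j]
                ivals.append((float(session.time_s[i]), float(end)))
                i = j + 1
            else:
                i += 1
        intervals[side] = ivals
    return ZoneOccupancy(intervals=intervals, seconds=seconds)


def closed_loop_epochs(
    occupancy: ZoneOccupancy, stim_side: str
) -> list[tuple[float, float]]:
    """Stimulation epochs of the closed loop.

    The laser switches on at zone entry and off at exit, so the epochs are
    exactly the stimulation-side zone intervals and total stimulation time
    equals T_S.
    """
    if stim_side not in SIDES:
        raise DataError(f"stim_side must be one of {SIDES}, got {stim_side!r}")
    return list(occupancy.intervals[stim_side])


def preference_score(t_s: float, t_ns: float) -> float:
    """PS = 100 * T_S / (T_S + T_NS); NaN when the animal visited no zone."""
    if t_s < 0 or t_ns < 0:
        raise DataError(f"zone times must be non-negative, got ({t_s}, {t_ns})")
    if t_s + t_ns == 0:
        return math.nan
    return 100.0 * t_s / (t_s + t_ns)


def normalized_preference(ps_t: float, ps_h: float) -> float:
    """NS = 100 * PS_testing / PS_habituation; NaN when PS_habituation = 0."""
    if math.isnan(ps_t) or math.isnan(ps_h) or ps_h == 0:
        return math.nan
    return 100.0 * ps_t / ps_h


def chamber_times(
    session: BehaviorSession, geometry: ArenaGeometry
) -> dict[str, float]:
    """Cumulative seconds per chamber (left, center, right); sums to duration."""
    x, _ = _clipped_positions(session, geometry)
    spans = _sample_spans(session.time_s)
    e1, e2 = geometry.chamber_edges_cm
    return {
        "left": float(spans[x < e1].sum()),
        "center": float(spans[(x >= e1) & (x < e2)].sum()),
        "right": float(spans[x >= e2].sum()),
    }


# ---------------------------------------------------------------------------
# protocol validation
# ---------------------------------------------------------------------------

_SESSION_TYPES = ("ToyToy", "ToyFemale")
_TRIAL_TYPES = ("habituation", "testing")


def _norm_side(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "-", "none", "nan"):
        return None
    return {"l": "left", "r": "right"}.get(s, s)


def session_protocol_check(sessions: pd.DataFrame | list[dict]) -> dict:
    """Validate the 4-trial counterbalanced 3CST protocol.

    Each animal must run habituation + testing for both session types
    (ToyToy, ToyFemale); stimulation is on only during testing trials with
    a side assigned.  Returns a report with per-animal issues and
    counterbalancing tallies (stimulation side, first session type).
    """
    df = pd.DataFrame(sessions)
    required = {"animal", "session", "trial", "stim"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"protocol table missing columns {sorted(missing)}")
    issues: list[str] = []
    side_tally: dict[str, int] = {"left": 0, "right": 0}
    first_session_tally: dict[str, int] = {s: 0 for s in _SESSION_TYPES}
    for animal, grp in df.groupby("animal", sort=False):
        if len(grp) != 4:
            issues.append(f"{animal}: expected 4 trials, found {len(grp)}")
        first = str(grp.iloc[0]["session"])
        if first in first_session_tally:
            first_session_tally[first] += 1
        for stype in _SESSION_TYPES:
            sub = grp[grp["session"].astype(str) == stype]
            for ttype in _TRIAL_TYPES:
                n = int((sub["trial"].astype(str).str.lower() == ttype).sum())
                if n != 1:
                    issues.append(
                        f"{animal}/{stype}: expected one {ttype} trial, found {n}"
                    )
        for row in grp.itertuples():
            stim_on = str(row.stim).strip().lower() in ("on", "true", "1")
            testing = str(row.trial).strip().lower() == "testing"
            side = _norm_side(getattr(row, "stim_side", None))
            if testing:
                if not stim_on:
                    issues.append(f"{animal}/{row.session}: testing trial without stim")
                if side not in SIDES:
                    issues.append(
                        f"{animal}/{row.session}: testing trial missing stim side"
                    )
                else:
                    side_tally[side] += 1
            else:
                if stim_on:
                    issues.append(f"{animal}/{row.session}: stim on in habituation")
                if side is not None:
                    issues.append(
                        f"{animal}/{row.session}: stim side set in habituation"
                    )
    return {
        "valid": not issues,
        "issues": issues,
        "counterbalance": {
            "stim_side": side_tally,
            "first_session": first_session_tally,
        },
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_trajectory(path, **meta) -> BehaviorSession:
    """Read a trajectory CSV with columns time_s, nose_x_cm, nose_y_cm."""
    df = pd.read_csv(path)
    required = {"time_s", "nose_x_cm", "nose_y_cm"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    return BehaviorSession(
        time_s=df["time_s"].to_numpy(),
        nose_x_cm=df["nose_x_cm"].to_numpy(),
        nose_y_cm=df["nose_y_cm"].to_numpy(),
        **meta,
    )


def save_trajectory(session: BehaviorSession, path) -> None:
    pd.DataFrame(
        {
            "time_s": session.time_s,
            "nose_x_cm": session.nose_x_cm,
            "nose_y_cm": session.nose_y_cm,
        }
    ).to_csv(path, index=False)
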
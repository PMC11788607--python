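"""Trajectory-derived measures.

Reaction time is the time from stimulus onset until the stylus first leaves
the start button's disk; movement time runs from that exit until the stylus
first lies inside a response button; initial velocity is the displacement
between the last sample inside the start disk and the first outside, divided
by the sample interval.  A change of mind is a trial whose first-exit side
(sign of x relative to the start center) differs from the side of the finally
registered response.

Boundary conventions: "inside the start button" means distance <= start
radius (boundary inclusive); "inside a response button" means distance
strictly < button radius.  A first exit exactly on the vertical midline
defers to the next off-midline sample, and counts as no change of mind if
none exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import DEFAULT_LAYOUT, Layout, Point, button_positions


@dataclass(frozen=True)
class TrialKinematics:
    """Per-trial kinematic summary; timing fields are None for miss trials."""

    rt_ms: Optional[float]
    movement_ms: Optional[float]
    initial_velocity_cm_s: Optional[float]
    change_of_mind: bool
    registered_choice: Optional[str]
    first_exit_point: Optional[Point]


def _as_arrays(trajectory) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(trajectory, pd.DataFrame):
        t = trajectory["t_ms"].to_numpy(float)
        x = trajectory["x_cm"].to_numpy(float)
        y = trajectory["y_cm"].to_numpy(float)
    else:
        t, x, y = (np.asarray(a, dtype=float) for a in trajectory)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if np.any(np.diff(t) < 0):
        raise ValueError("trajectory timestamps must be non-decreasing")
    return t, x, y


def _first_exit_index(x, y, layout: Layout) -> Optional[int]:
    d = np.hypot(x - layout.start_center.x, y - layout.start_center.y)
    outside = np.flatnonzero(d > layout.start_radius)
    return int(outside[0]) if outside.size else None


def _registration_index(x, y, layout: Layout, condition: str) -> Optional[Tuple[int, str]]:
    left, right = button_positions(condition, layout)
    d_left = np.hypot(x - left.x, y - left.y)
    d_right = np.hypot(x - right.x, y - right.y)
    inside = np.flatnonzero((d_left < layout.button_radius) | (d_right < layout.button_radius))
    if not inside.size:
        return None
    i = int(inside[0])
    side = "left" if d_left[i] < layout.button_radius else "right"
    return i, side


def reaction_time(trajectory, layout: Layout = DEFAULT_LAYOUT) -> Optional[float]:
    """Timestamp (ms) of the first sample outside the start disk, or None."""
    t, x, y = _as_arrays(trajectory)
    i = _first_exit_index(x, y, layout)
    return None if i is None else float(t[i])


def movement_time(
    trajectory, layout: Layout = DEFAULT_LAYOUT, condition: str = "left_closer"
) -> Optional[float]:
    """Time (ms) from start-disk exit to first sample inside a response button."""
    t, x, y = _as_arrays(trajectory)
    i_exit = _first_exit_index(x, y, layout)
    if i_exit is None:
        return None
    reg = _registration_index(x, y, layout, condition)
    if reg is None:
        return None
    return float(t[reg[0]] - t[i_exit])


def initial_velocity(trajectory, layout: Layout = DEFAULT_LAYOUT) -> Optional[float]:
    """Instantaneous speed (cm/s) across the start-disk boundary crossing."""
    t, x, y = _as_arrays(trajectory)
    i = _first_exit_index(x, y, layout)
    if i is None or i == 0:
        return None
    dt_s = (t[i] - t[i - 1]) / 1000.0
    if dt_s <= 0:
        return None
    dist = float(np.hypot(x[i] - x[i - 1], y[i] - y[i - 1]))
    return dist / dt_s


def classify_change_of_mind(
    trajectory, registered_choice: str, layout: Layout = DEFAULT_LAYOUT
) -> bool:
    """True if the initial movement side differs from the registered choice side."""
    if registered_choice not in ("left", "right"):
        raise ValueError(f"registered_choice must be 'left' or 'right', got {registered_choice!r}")
    t, x, y = _as_arrays(trajectory)
    i = _first_exit_index(x, y, layout)
    if i is None:
        return False
    dx = x[i:] - layout.start_center.x
    off_mid = np.flatnonzero(dx != 0.0)
    if not off_mid.size:
        return False
    initial_side = "right" if dx[off_mid[0]] > 0 else "left"
    return initial_side != registered_choice


def trial_kinematics(
    trajectory, layout: Layout = DEFAULT_LAYOUT, condition: str = "left_closer"
) -> TrialKinematics:
    """All kinematic measures of one trial in a single pass."""
    t, x, y = _as_arrays(trajectory)
    i_exit = _first_exit_index(x, y, layout)
    if i_exit is None:
        return TrialKinematics(None, None, None, False, None, None)
    reg = _registration_index(x, y, layout, condition)
    if reg is None:
        return TrialKinematics(float(t[i_exit]), None, None, False, None,
                               Point(float(x[i_exit]), float(y[i_exit])))
    i_reg, side = reg
    vel = initial_velocity((t, x, y), layout)
    com = classify_change_of_mind((t, x, y), side, layout)
    return TrialKinematics(
        rt_ms=float(t[i_exit]),
        movement_ms=float(t[i_reg] - t[i_exit]),
        initial_velocity_cm_s=vel,
        change_of_mind=com,
        registered_choice=side,
        first_exit_point=Point(float(x[i_exit]), float(y[i_exit])),
    )


def _completed(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[(trials["response"] != "miss") & trials["rt_ms"].notna()]


def rt_summary(trials: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """The median-of-medians reaction-time summaries.

    Per stimulus level: for each (task, block, level), the median RT per
    participant, then the mean of those medians across participants.  Also an
    overall per-(task, block) summary of the participant medians across all
    levels.  Miss trials are excluded from both.
    """
    ok = _completed(trials)
    per_level = (
        ok.groupby(["task", "block", "stimulus_level", "participant_id"])["rt_ms"]
        .median()
        .groupby(["task", "block", "stimulus_level"])
        .mean()
        .rename("mean_median_rt_ms")
        .reset_index()
    )
    overall = (
        ok.groupby(["task", "block", "participant_id"])["rt_ms"]
        .median()
        .groupby(["task", "block"])
        .mean()
        .rename("mean_median_rt_ms")
        .reset_index()
    )
    return per_level, overall


def movement_time_summary(trials: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-of-participant-median movement times, by near/far reach and by block.

    The near/far split pools both tasks and blocks, mirroring how the
    movement-cost asymmetry is summarized; the second table is per
    (task, block) across all trials.
    """
    ok = _completed(trials).copy()
    near = (
        (ok["condition"] == "left_closer") & (ok["response"] == "left")
    ) | ((ok["condition"] == "right_closer") & (ok["response"] == "right"))
    ok["reach"] = np.where(near, "near", "far")
    by_reach = (
        ok.groupby(["reach", "participant_id"])["movement_ms"]
        .median()
        .groupby("reach")
        .mean()
        .rename("mean_median_movement_ms")
        .reset_index()
    )
    by_block = (
        ok.groupby(["task", "block", "participant_id"])["movement_ms"]
        .median()
        .groupby(["task", "block"])
        .mean()
        .rename("mean_median_movement_ms")
        .reset_index()
    )
    return by_reach, by_block


def velocity_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean across participants of the median initial velocity, per (task, block)."""
    ok = _completed(trials)
    return (
        ok.groupby(["task", "block", "participant_id"])["initial_velocity_cm_s"]
        .median()
        .groupby(["task", "block"])
        .mean()
        .rename("mean_median_initial_velocity_cm_s")
        .reset_index()
    )


def change_of_mind_rate(trials: pd.DataFrame) -> float:
    """Fraction of completed trials classified as changes of mind."""
    ok = _completed(trials)
    if not len(ok):
        return float("nan")
    return float(ok["change_of_mind"].mean())
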
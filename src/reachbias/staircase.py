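"""Adaptive interleaved staircases.

Each block of the experiment runs four fixed-length staircases — one per
(condition x starting sign) cell — interleaved in random order.  The update
rule is 1-up/1-down on the *response* (not on correctness): a 'left' response
moves the next level of that staircase by one step towards rightward
evidence, and vice versa, which concentrates sampling around the stimulus
level where the observer answers left and right equally often.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import kinematics
from .geometry import CONDITIONS, DEFAULT_LAYOUT, Layout
from .stimuli import check_task

RESPONSES = ("left", "right", "miss")
BLOCKS = ("main", "control")

#: Staircase design per task: starting level magnitude, step, and hard limit.
TASK_STAIRCASE = {
    "motion": {"start": 50.0, "step": 5.0, "limit": 100.0},
    "orientation": {"start": 40.0, "step": 2.0, "limit": 80.0},
}

TRIALS_PER_STAIRCASE = 75


@dataclass(frozen=True)
class StaircaseConfig:
    start_level: float
    step: float
    limits: Tuple[float, float]
    n_trials: int = TRIALS_PER_STAIRCASE
    condition: str = "left_closer"
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.limits
        if not lo <= self.start_level <= hi:
            raise ValueError(f"start_level {self.start_level} outside limits {self.limits}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class StaircaseState:
    """One adaptive track: its config, current level, and trial history."""

    config: StaircaseConfig
    current_level: float = field(init=False)
    trials_done: int = field(init=False, default=0)
    history: List[Tuple[float, str]] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        self.current_level = self.config.start_level

    @property
    def exhausted(self) -> bool:
        return self.trials_done >= self.config.n_trials

    @property
    def remaining(self) -> int:
        return self.config.n_trials - self.trials_done


def make_block_staircases(
    task: str, n_trials: int = TRIALS_PER_STAIRCASE
) -> List[StaircaseState]:
    """The four staircases of one block: (condition x starting sign).

    Motion starts at +/-50% coherence with 5% steps and +/-100% limits;
    orientation at +/-40 deg difference with 2 deg steps and +/-80 deg limits.
    """
    check_task(task)
    d = TASK_STAIRCASE[task]
    states = []
    for condition in CONDITIONS:
        for sign, tag in ((-1.0, "neg"), (+1.0, "pos")):
            cfg = StaircaseConfig(
                start_level=sign * d["start"],
                step=d["step"],
                limits=(-d["limit"], d["limit"]),
                n_trials=n_trials,
                condition=condition,
                label=f"{condition}_{tag}",
            )
            states.append(StaircaseState(cfg))
    return states


def staircase_update(state: StaircaseState, response: str) -> StaircaseState:
    """Consume one trial at the current level and move the staircase.

    'left' raises the level by one step (more rightward evidence next),
    'right' lowers it, and a miss leaves it unchanged while still consuming
    one of the staircase's trials.  Levels are clipped at the limits.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}; valid responses are {RESPONSES}")
    if state.exhausted:
        raise RuntimeError(
            f"staircase {state.config.label or '?'} already ran its "
            f"{state.config.n_trials} trials"
        )
    state.history.append((state.current_level, response))
    step = {"left": state.config.step, "right": -state.config.step, "miss": 0.0}[response]
    lo, hi = state.config.limits
    state.current_level = float(min(hi, max(lo, state.current_level + step)))
    state.trials_done += 1
    return state


def interleave_schedule(
    states: Sequence[StaircaseState], rng: np.random.Generator
) -> List[int]:
    """Random interleaving: draw uniformly among staircases with trials left.

    Returns the ordered sequence of staircase indices; each index appears
    exactly ``n_trials`` times.
    """
    if any(s.trials_done for s in states):
        raise ValueError("interleave_schedule expects fresh staircases")
    remaining = [s.config.n_trials for s in states]
    schedule: List[int] = []
    while True:
        active = [i for i, r in enumerate(remaining) if r > 0]
        if not active:
            return schedule
        idx = active[int(rng.integers(len(active)))]
        remaining[idx] -= 1
        schedule.append(idx)


def run_block(
    observer,
    task: str,
    block: str,
    layout: Layout = DEFAULT_LAYOUT,
    seed: int | np.random.SeedSequence = 0,
    n_trials_per_staircase: int = TRIALS_PER_STAIRCASE,
    collect_trajectories: bool = True,
    participant_id: int = 0,
    seed_path: str = "",
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Run one 300-trial block against an observer.

    ``observer`` must provide ``simulate_trial(level, condition, block,
    layout, rng_resp, rng_motor, collect_trajectory)`` returning a
    ``(response, trajectory)`` pair where ``trajectory`` is a stylus trace
    (``t_ms, x_cm, y_cm``) or None.  Kinematic measures in the returned trial
    log are derived from the trace by the same classifiers used for analysis.

    Returns ``(trials, trajectories)``; ``trajectories`` is a long-format
    frame keyed by ``trial_index`` (None when not collected).
    """
    if block not in BLOCKS:
        raise ValueError(f"unknown block {block!r}; valid blocks are {BLOCKS}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_ss, resp_ss, motor_ss = ss.spawn(3)
    rng_sched = np.random.default_rng(sched_ss)
    rng_resp = np.random.default_rng(resp_ss)
    rng_motor = np.random.default_rng(motor_ss)

    states = make_block_staircases(task, n_trials_per_staircase)
    schedule = interleave_schedule(states, rng_sched)

    rows = []
    traj_frames: List[pd.DataFrame] = []
    for trial_index, sc_idx in enumerate(schedule):
        state = states[sc_idx]
        level = state.current_level
        condition = state.config.condition
        response, trajectory = observer.simulate_trial(
            level, condition, block, layout, rng_resp, rng_motor, collect_trajectories
        )
        staircase_update(state, response)

        rt_ms = mt_ms = vel = np.nan
        com = np.nan
        if trajectory is not None:
            meas = kinematics.trial_kinematics(trajectory, layout, condition)
            rt_ms = np.nan if meas.rt_ms is None else meas.rt_ms
            mt_ms = np.nan if meas.movement_ms is None else meas.movement_ms
            vel = np.nan if meas.initial_velocity_cm_s is None else meas.initial_velocity_cm_s
            com = float(meas.change_of_mind)
            traj = trajectory.copy()
            traj.insert(0, "trial_index", trial_index)
            traj_frames.append(traj)
        rows.append(
            (
                participant_id, task, block, condition, state.config.label,
                trial_index, level, response, rt_ms, mt_ms, vel, com, seed_path,
            )
        )

    trials = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "task", "block", "condition", "staircase_id",
            "trial_index", "stimulus_level", "response", "rt_ms", "movement_ms",
            "initial_velocity_cm_s", "change_of_mind", "seed_path",
        ],
    )
    trajectories = (
        pd.concat(traj_frames, ignore_index=True) if traj_frames else None
    )
    return trials, trajectories
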
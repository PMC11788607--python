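"""File formats and run configuration.

The trial log is a flat CSV (UTF-8, comma-separated, '.' decimal) with one
row per trial; trajectories live in a separate long-format CSV keyed by
(participant_id, task, block, trial_index) so the trial log stays compact.
Units are fixed: stimulus levels in % coherence or degrees, times in ms,
velocities in cm/s, coordinates in cm — embedded in the column names where
applicable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .geometry import CONDITIONS, Layout
from .staircase import BLOCKS, RESPONSES
from .stimuli import TASK_LIMITS, TASKS

TRIAL_COLUMNS: List[str] = [
    "participant_id", "task", "block", "condition", "staircase_id",
    "trial_index", "stimulus_level", "response", "rt_ms", "movement_ms",
    "initial_velocity_cm_s", "change_of_mind", "seed_path",
]

TRAJECTORY_COLUMNS: List[str] = [
    "participant_id", "task", "block", "trial_index", "t_ms", "x_cm", "y_cm",
]

_TIMING_COLUMNS = ["rt_ms", "movement_ms", "initial_velocity_cm_s"]


class TrialLogError(ValueError):
    """Schema violation in a trial log, with row-numbered messages."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        shown = errors[:20]
        more = f" (+{len(errors) - 20} more)" if len(errors) > 20 else ""
        super().__init__("invalid trial log:\n  " + "\n  ".join(shown) + more)


def validate_trial_log(trials: pd.DataFrame) -> None:
    """Check the trial-log contract; raise TrialLogError listing bad rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialLogError([f"missing required column(s): {', '.join(missing)}"])
    errors: List[str] = []

    def bad(mask: pd.Series, msg: str) -> None:
        for row in trials.index[mask][:50]:
            errors.append(f"row {row}: {msg} (got {trials.loc[row, col]!r})")

    col = "task"
    bad(~trials[col].isin(TASKS), f"task must be one of {TASKS}")
    col = "block"
    bad(~trials[col].isin(BLOCKS), f"block must be one of {BLOCKS}")
    col = "condition"
    bad(~trials[col].isin(CONDITIONS), f"condition must be one of {CONDITIONS}")
    col = "response"
    bad(~trials[col].isin(RESPONSES), f"response must be one of {RESPONSES}")

    col = "stimulus_level"
    for task in TASKS:
        limit = TASK_LIMITS[task]
        sel = trials["task"] == task
        bad(sel & (trials[col].abs() > limit), f"{task} level must be within +/-{limit}")

    miss = trials["response"] == "miss"
    for col in _TIMING_COLUMNS:
        bad(miss & trials[col].notna(), "miss trials must have empty timing fields")

    dup = trials.duplicated(subset=["participant_id", "task", "block", "trial_index"])
    for row in trials.index[dup][:50]:
        errors.append(f"row {row}: duplicate trial_index within (participant, task, block)")
    if errors:
        raise TrialLogError(errors)


def write_trial_log(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trial_log(trials)
    trials.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV; unknown extra columns are preserved."""
    trials = pd.read_csv(path)
    validate_trial_log(trials)
    return trials


def write_trajectories(trajectories: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in trajectories.columns]
    if missing:
        raise ValueError(f"trajectory table missing column(s): {', '.join(missing)}")
    trajectories.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    traj = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.columns]
    if missing:
        raise ValueError(f"trajectory table missing column(s): {', '.join(missing)}")
    return traj


@dataclass
class RunConfig:
    """Configuration of a simulate -> fit -> analyze -> report run."""

    n_participants: int = 24
    tasks: List[str] = field(default_factory=lambda: list(TASKS))
    blocks: List[str] = field(default_factory=lambda: list(BLOCKS))
    seed: int = 0
    n_boot: int = 199
    n_perm: int = 10_000
    lapse_criterion: float = 0.05
    collect_trajectories: bool = False
    layout: Optional[dict] = None            # Layout.to_dict overrides
    observer_overrides: Dict[str, dict] = field(default_factory=dict)
    spread_overrides: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r} in config")
        for b in self.blocks:
            if b not in BLOCKS:
                raise ValueError(f"unknown block {b!r} in config")
        if not 0.0 < self.lapse_criterion < 0.5:
            raise ValueError("lapse_criterion must be in (0, 0.5)")

    def get_layout(self) -> Layout:
        return Layout.from_dict(self.layout) if self.layout else Layout()

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "tasks": list(self.tasks),
            "blocks": list(self.blocks),
            "seed": self.seed,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "lapse_criterion": self.lapse_criterion,
            "collect_trajectories": self.collect_trajectories,
            "layout": self.layout,
            "observer_overrides": self.observer_overrides,
            "spread_overrides": self.spread_overrides,
        }

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


CONFIG_TEMPLATE = """\
# reachbias run configuration
n_participants: 24        # cohort size
tasks: [motion, orientation]
blocks: [main, control]
seed: 0                   # master seed; all randomness derives from it
n_boot: 199               # parametric-bootstrap draws for threshold CIs
n_perm: 10000             # permutations for the cross-task Spearman p-value
lapse_criterion: 0.05     # participants with any lapse above this are flagged
collect_trajectories: false   # also write the (large) stylus-trace CSV
# layout:                 # optional geometry overrides (cm / Hz)
#   start_center: [0.0, 7.5]
#   start_radius: 2.5
# observer_overrides:     # optional per-task observer parameter overrides
#   motion: {delta: 9.9, control_delta: 3.1}
# spread_overrides:       # optional per-task cohort-spread overrides
#   motion: {delta_sd: 8.0}
"""
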
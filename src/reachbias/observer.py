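"""Synthetic participant generating choices, reaction times and stylus traces.

The observer is a cumulative-Gaussian chooser whose threshold shifts with the
button configuration: with baseline point of subjective equality ``m0`` and a
closeness-attraction magnitude ``delta``, the condition thresholds are
``m0 + delta/2`` when the left button is closer and ``m0 - delta/2`` when the
right one is, so the implied decision bias (threshold_right_closer minus
threshold_left_closer) equals ``-delta`` exactly.  Control blocks use
``control_delta`` instead, so a bias-free control is ``control_delta = 0``.

Reaction times are lognormal around a peaked function of the stimulus level
(slowest near the point of maximal uncertainty, slightly off zero), and
trajectories are constant-speed polyline reaches sampled on the touchscreen's
60 Hz grid, with rare change-of-mind excursions whose initial heading targets
the other button.  These motor models are deliberately simple: they give the
kinematic classifiers structured input, they do not model motor control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import staircase as _staircase
from .geometry import (
    CONDITIONS,
    DEFAULT_LAYOUT,
    Layout,
    button_positions,
    near_side,
)
from .stimuli import TASKS, check_task

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class RtModel:
    """Lognormal reaction-time model: median = base + gain * exp(-|x - peak|/tau)."""

    base_ms: float = 1000.0
    gain_ms: float = 450.0
    tau: float = 40.0           # stimulus units; decay scale of the uncertainty peak
    peak_offset: float = -5.0   # stimulus units; where RTs are longest
    sd_log: float = 0.3


@dataclass(frozen=True)
class MoveModel:
    """Constant-speed reach model with a cautious-start factor for control blocks."""

    speed_near_cm_s: float = 77.0
    speed_far_cm_s: float = 87.0
    control_speed_factor: float = 0.8
    speed_jitter_sd_log: float = 0.1


@dataclass(frozen=True)
class ObserverParams:
    """Full parameter set of one synthetic participant (one task).

    ``m0``, ``delta``, ``sigma`` are in the task's stimulus units (% coherence
    or degrees).  ``lapse`` compresses both asymptotes symmetrically;
    ``miss_rate`` is the probability of no response within the deadline.
    """

    m0: float = 0.0
    delta: float = 0.0
    sigma: float = 30.0
    lapse: float = 0.01
    miss_rate: float = 0.01
    rt: RtModel = field(default_factory=RtModel)
    move: MoveModel = field(default_factory=MoveModel)
    com_prob: float = 0.01
    control_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= 0.49:
            raise ValueError("lapse must be in [0, 0.49]")
        if not 0.0 <= self.miss_rate <= 0.2:
            raise ValueError("miss_rate must be in [0, 0.2]")
        if not 0.0 <= self.com_prob <= 0.1:
            raise ValueError("com_prob must be in [0, 0.1]")


def condition_threshold(params: ObserverParams, condition: str, block: str) -> float:
    """The observer's 50%-rightward point for one condition and block."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    d = params.delta if block == "main" else params.control_delta
    return params.m0 + (d / 2.0 if condition == "left_closer" else -d / 2.0)


def p_right(x: float, condition: str, params: ObserverParams, block: str = "main") -> float:
    """Probability of a rightward choice at stimulus level ``x``."""
    m = condition_threshold(params, condition, block)
    lam = params.lapse
    phi = 0.5 * (1.0 + math.erf((x - m) / (params.sigma * _SQRT2)))
    return lam + (1.0 - 2.0 * lam) * phi


def sample_response(
    x: float,
    condition: str,
    block: str,
    params: ObserverParams,
    rng: np.random.Generator,
) -> str:
    """Draw one response: miss with ``miss_rate``, else right with ``p_right``."""
    if params.miss_rate > 0.0 and rng.random() < params.miss_rate:
        return "miss"
    return "right" if rng.random() < p_right(x, condition, params, block) else "left"


def sample_rt(x: float, params: ObserverParams, rng: np.random.Generator) -> float:
    """Draw one reaction time (ms), slowest near the uncertainty peak."""
    r = params.rt
    median = r.base_ms + r.gain_ms * math.exp(-abs(x - r.peak_offset) / r.tau)
    return median * math.exp(rng.normal(0.0, r.sd_log))


def _polyline_trace(
    waypoints: Sequence[Tuple[float, float]],
    speed_cm_s: float,
    rt_ms: float,
    layout: Layout,
) -> pd.DataFrame:
    """Sample a constant-speed walk along waypoints on the layout's time grid.

    The stylus dwells at the first waypoint until ``rt_ms``, then advances by
    ``speed * dt`` per sample; the final sample is placed exactly on the last
    waypoint so a response is always registered.
    """
    dt = layout.dt_ms
    pts = np.asarray(waypoints, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    step = speed_cm_s * dt / 1000.0

    n_dwell = max(1, int(math.ceil(rt_ms / dt)))
    n_move = int(math.ceil(total / step)) if step > 0 else 1
    n = n_dwell + n_move + 1
    t = np.arange(n) * dt
    xy = np.empty((n, 2))
    xy[:n_dwell] = pts[0]
    s = np.minimum(np.arange(1, n_move + 1) * step, total)
    xy[n_dwell : n_dwell + n_move, 0] = np.interp(s, cum, pts[:, 0])
    xy[n_dwell : n_dwell + n_move, 1] = np.interp(s, cum, pts[:, 1])
    xy[-1] = pts[-1]
    return pd.DataFrame({"t_ms": t, "x_cm": xy[:, 0], "y_cm": xy[:, 1]})


def sample_trajectory(
    choice: str,
    condition: str,
    block: str,
    layout: Layout,
    params: ObserverParams,
    rng: np.random.Generator,
    rt_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Generate one stylus trace for a completed (non-miss) trial.

    With probability ``com_prob`` the reach first heads towards the *other*
    button before redirecting to the chosen one; the excursion length is
    drawn beyond the start-button radius so the change of mind is visible to
    the first-exit classifier.  Control blocks scale the reach speed down by
    ``control_speed_factor`` (a more cautious start while the buttons appear).
    """
    if choice not in ("left", "right"):
        raise ValueError(f"choice must be 'left' or 'right', got {choice!r}")
    if rt_ms is None:
        rt_ms = sample_rt(0.0, params, rng)
    left, right = button_positions(condition, layout)
    target = left if choice == "left" else right
    other = right if choice == "left" else left
    mv = params.move
    speed = mv.speed_near_cm_s if choice == near_side(condition) else mv.speed_far_cm_s
    speed *= math.exp(rng.normal(0.0, mv.speed_jitter_sd_log))
    if block == "control":
        speed *= mv.control_speed_factor

    start = layout.start_center.as_tuple()
    waypoints = [start]
    if params.com_prob > 0.0 and rng.random() < params.com_prob:
        lo = layout.start_radius + 0.3
        d_com = rng.uniform(lo, max(4.0, lo + 1.0))
        ux = (other.x - start[0], other.y - start[1])
        norm = math.hypot(*ux)
        waypoints.append((start[0] + ux[0] / norm * d_com, start[1] + ux[1] / norm * d_com))
    waypoints.append(target.as_tuple())
    return _polyline_trace(waypoints, speed, rt_ms, layout)


class SyntheticObserver:
    """Bundles ObserverParams behind the trial-sampling contract of ``run_block``."""

    def __init__(self, params: ObserverParams):
        self.params = params

    def simulate_trial(
        self,
        level: float,
        condition: str,
        block: str,
        layout: Layout,
        rng_resp: np.random.Generator,
        rng_motor: np.random.Generator,
        collect_trajectory: bool = True,
    ) -> Tuple[str, Optional[pd.DataFrame]]:
        response = sample_response(level, condition, block, self.params, rng_resp)
        trajectory = None
        if collect_trajectory and response != "miss":
            rt = sample_rt(level, self.params, rng_motor)
            trajectory = sample_trajectory(
                response, condition, block, layout, self.params, rng_motor, rt
            )
        return response, trajectory


# ---------------------------------------------------------------------------
# Study-condition presets and cohort simulation
# ---------------------------------------------------------------------------

#: Per-task observer defaults emulating the group-level fitted parameters:
#: motion thresholds around -8.7/+1.1 (main) with width ~97% and a small
#: residual control-block shift; orientation thresholds 3.8/10.8 with width
#: ~49 deg.  sigma = width / 3.2897.
TASK_OBSERVERS: Dict[str, ObserverParams] = {
    "motion": ObserverParams(
        m0=-3.8, delta=9.9, sigma=29.5, lapse=0.01, miss_rate=0.01,
        rt=RtModel(base_ms=1000.0, gain_ms=450.0, tau=40.0, peak_offset=-5.0, sd_log=0.3),
        move=MoveModel(), com_prob=0.01, control_delta=3.1,
    ),
    "orientation": ObserverParams(
        m0=7.3, delta=7.0, sigma=14.9, lapse=0.01, miss_rate=0.01,
        rt=RtModel(base_ms=780.0, gain_ms=340.0, tau=20.0, peak_offset=2.0, sd_log=0.3),
        move=MoveModel(), com_prob=0.01, control_delta=1.0,
    ),
}


@dataclass(frozen=True)
class CohortSpread:
    """Between-participant variability of the observer parameters.

    ``m0`` and ``delta`` vary normally around the task preset; ``sigma``
    varies lognormally.  ``cross_task_r`` correlates a participant's bias
    magnitudes across tasks (0 by default: no idiosyncratic bias trait).
    """

    m0_sd: float = 8.0
    delta_sd: float = 8.0
    sigma_sd_log: float = 0.4
    cross_task_r: float = 0.0


#: Spreads matched to the between-participant SDs of the fitted parameters.
TASK_SPREADS: Dict[str, CohortSpread] = {
    "motion": CohortSpread(m0_sd=8.0, delta_sd=8.0, sigma_sd_log=0.4),
    "orientation": CohortSpread(m0_sd=4.0, delta_sd=5.0, sigma_sd_log=0.5),
}


def default_observer(task: str) -> ObserverParams:
    check_task(task)
    return TASK_OBSERVERS[task]


def sample_participant_params(
    base: ObserverParams,
    spread: CohortSpread,
    rng: np.random.Generator,
    delta_z: Optional[float] = None,
) -> ObserverParams:
    """Draw one participant's parameters around a task preset.

    ``delta_z`` optionally supplies the standard-normal deviate for the bias
    draw, which lets callers correlate deltas across tasks.
    """
    z = rng.normal() if delta_z is None else delta_z
    return replace(
        base,
        m0=base.m0 + spread.m0_sd * rng.normal(),
        delta=base.delta + spread.delta_sd * z,
        sigma=base.sigma * math.exp(spread.sigma_sd_log * rng.normal()),
    )


def simulate_experiment(
    n_participants: int = 24,
    tasks: Sequence[str] = TASKS,
    blocks: Sequence[str] = _staircase.BLOCKS,
    master_seed: int | np.random.SeedSequence = 0,
    layout: Layout = DEFAULT_LAYOUT,
    observer_params: Optional[Dict[str, ObserverParams]] = None,
    spread: Optional[Dict[str, CohortSpread]] = None,
    collect_trajectories: bool = True,
    n_trials_per_staircase: int = _staircase.TRIALS_PER_STAIRCASE,
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Simulate a full cohort: participants x tasks x blocks of 300 trials.

    Seeds are derived deterministically (master -> participant -> block), so
    the same master seed reproduces the data set exactly.  Pass
    ``spread=None`` for heterogeneous cohorts drawn from the task presets, or
    explicit zero spreads for identical participants.

    Returns ``(trials, trajectories)`` in the trial-log schema; trajectories
    are long-format (participant_id, task, block, trial_index, t_ms, x_cm,
    y_cm) or None when not collected.
    """
    for task in tasks:
        check_task(task)
    base = dict(TASK_OBSERVERS)
    if observer_params:
        base.update(observer_params)
    spreads = dict(TASK_SPREADS)
    if spread:
        spreads.update(spread)

    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    participant_seeds = ss.spawn(n_participants)
    all_trials = []
    all_trajs = []
    for pid, pss in enumerate(participant_seeds):
        n_cells = len(tasks) * len(blocks)
        children = pss.spawn(n_cells + 1)
        rng_params = np.random.default_rng(children[0])
        # one shared deviate per participant drives the cross-task bias correlation
        shared_z = rng_params.normal()
        params_by_task: Dict[str, ObserverParams] = {}
        for task in tasks:
            sp = spreads[task]
            own_z = rng_params.normal()
            r = sp.cross_task_r
            z = r * shared_z + math.sqrt(max(0.0, 1.0 - r * r)) * own_z
            params_by_task[task] = sample_participant_params(base[task], sp, rng_params, z)
        cell = 1
        for task in tasks:
            obs = SyntheticObserver(params_by_task[task])
            for block in blocks:
                trials, trajs = _staircase.run_block(
                    obs,
                    task,
                    block,
                    layout=layout,
                    seed=children[cell],
                    n_trials_per_staircase=n_trials_per_staircase,
                    collect_trajectories=collect_trajectories,
                    participant_id=pid,
                    seed_path=f"p{pid}/{task}/{block}",
                )
                cell += 1
                all_trials.append(trials)
                if trajs is not None:
                    trajs.insert(0, "block", block)
                    trajs.insert(0, "task", task)
                    trajs.insert(0, "participant_id", pid)
                    all_trajs.append(trajs)
    trials = pd.concat(all_trials, ignore_index=True)
    trajectories = pd.concat(all_trajs, ignore_index=True) if all_trajs else None
    return trials, trajectories
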
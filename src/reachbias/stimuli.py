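"""Stimulus parameterization for the two discrimination tasks.

Both tasks express the trial's perceptual evidence as a single signed
*stimulus level*:

* motion task — percentage of coherently moving dots, negative for leftward
  motion, in [-100, 100];
* orientation task — orientation difference between the two Gabor patches in
  degrees (left angle minus right angle, both measured from vertical),
  negative when the left Gabor is the more vertical one, in [-80, 80].

The random-dot kinematogram generator produces dot *coordinates* only (no
rendering): three alternating sets of dots, limited dot lifetime via random
reallocation, and mirrored noise directions so that the noise dots carry no
net horizontal motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

TASKS = ("motion", "orientation")

#: Hard staircase limits per task (absolute stimulus level).
TASK_LIMITS = {"motion": 100.0, "orientation": 80.0}

#: Units in which stimulus levels are expressed, per task.
TASK_UNITS = {"motion": "% coherence", "orientation": "deg orientation difference"}


def check_task(task: str) -> None:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks are {TASKS}")


def check_level(task: str, value: float) -> None:
    check_task(task)
    limit = TASK_LIMITS[task]
    if not (-limit <= value <= limit):
        raise ValueError(f"{task} stimulus level {value} outside [-{limit}, {limit}]")


def gabor_angles(difference: float) -> tuple[float, float]:
    """Orientations (from vertical) of the left and right Gabor for a signed difference.

    The two angles are symmetric about 45 deg and the difference is defined as
    left minus right, so a positive difference means the right Gabor is the
    more vertical one.  |difference| <= 80 keeps both angles in the generated
    [5, 85] deg range.
    """
    if abs(difference) > 80:
        raise ValueError(
            f"orientation difference {difference} deg would push a Gabor outside "
            "the generated 5-85 deg range (|difference| must be <= 80)"
        )
    half = difference / 2.0
    return (45.0 + half, 45.0 - half)


def expected_dot_lifetime(realloc_prob: float, frame_rate: float) -> float:
    """Expected on-screen lifetime of a dot, in ms.

    Reallocation is a per-frame Bernoulli event, so the lifetime is geometric
    with mean 1/realloc_prob frames.
    """
    if not (0.0 < realloc_prob <= 1.0):
        raise ValueError(f"realloc_prob must be in (0, 1], got {realloc_prob}")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return (1.0 / realloc_prob) * (1000.0 / frame_rate)


@dataclass(frozen=True)
class RdkParams:
    """Parameters of the random-dot kinematogram.

    ``n_dots`` are split into ``n_sets`` interleaved sets displayed on
    alternating video frames; a set therefore updates every ``n_sets``-th
    frame, and each dot travels ``dot_speed * n_sets / frame_rate`` cm per
    update so that its on-screen speed equals ``dot_speed``.
    """

    n_dots: int = 102
    n_sets: int = 3
    dot_speed: float = 16.5          # cm/s on screen
    aperture_radius: float = 8.5     # cm; the display cloud radius
    realloc_prob: float = 1.0 / 6.0  # per set-update
    frame_rate: float = 60.0         # Hz
    duration: float = 3.0            # s
    aperture_diameter_generator: float = 24.6  # cm; generator-unit figure, metadata only

    def __post_init__(self) -> None:
        if not (0.0 < self.realloc_prob <= 1.0):
            raise ValueError("realloc_prob must be in (0, 1]")
        if self.n_dots % self.n_sets != 0:
            raise ValueError(
                f"n_dots ({self.n_dots}) must be divisible by n_sets ({self.n_sets})"
            )
        if min(self.dot_speed, self.aperture_radius, self.frame_rate, self.duration) <= 0:
            raise ValueError("dot_speed, aperture_radius, frame_rate, duration must be positive")

    @property
    def dots_per_set(self) -> int:
        return self.n_dots // self.n_sets

    @property
    def step_cm(self) -> float:
        """Displacement of a surviving dot per set-update, in cm."""
        return self.dot_speed * self.n_sets / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def rdk_assign_directions(
    n_active_dots: int, coherence: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-dot motion directions (degrees) for one set of dots.

    ``round(|coherence|/100 * n)`` dots (round half away from zero) move
    coherently at 0 deg (rightward) for positive coherence or 180 deg for
    negative.  The remaining noise dots are assigned in mirrored pairs
    (theta, 180 - theta) so their summed horizontal unit components cancel
    exactly; an odd leftover dot moves straight up or down with equal
    probability.
    """
    if abs(coherence) > 100:
        raise ValueError(f"|coherence| must be <= 100, got {coherence}")
    n_coh = _round_half_away(abs(coherence) / 100.0 * n_active_dots)
    n_coh = min(n_coh, n_active_dots)
    signal_dir = 0.0 if coherence >= 0 else 180.0
    directions = np.full(n_active_dots, signal_dir)
    n_noise = n_active_dots - n_coh
    n_pairs = n_noise // 2
    theta = rng.uniform(0.0, 360.0, size=n_pairs)
    noise = np.empty(n_noise)
    noise[:n_pairs] = theta
    noise[n_pairs : 2 * n_pairs] = 180.0 - theta
    if n_noise % 2:
        noise[-1] = 90.0 if rng.random() < 0.5 else -90.0
    directions[n_coh:] = noise
    return directions


def _uniform_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def rdk_generate(
    params: RdkParams, coherence: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Generate a full kinematogram as a table of dot coordinates.

    Returns one row per displayed dot per frame with columns
    ``frame, set, dot, x_cm, y_cm, reallocated, expired``.  Coordinates are
    relative to the aperture center.  ``reallocated`` marks updates where the
    dot was redrawn uniformly inside the aperture (lifetime expiry or leaving
    the aperture); ``expired`` marks the lifetime-expiry events only, so the
    geometric lifetime can be estimated as updates-per-expiry.
    """
    check_level("motion", coherence)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per = params.dots_per_set
    n_frames = params.n_frames
    step = params.step_cm
    R = params.aperture_radius

    frames_out, sets_out, dots_out, xs, ys = [], [], [], [], []
    realloc_out, expired_out = [], []
    dot_ids = np.arange(n_per)
    for s in range(params.n_sets):
        pos = _uniform_disk(n_per, R, rng)
        dirs = np.deg2rad(rdk_assign_directions(n_per, coherence, rng))
        vel = step * np.column_stack([np.cos(dirs), np.sin(dirs)])
        display_frames = range(s, n_frames, params.n_sets)
        for i, f in enumerate(display_frames):
            realloc = np.zeros(n_per, dtype=bool)
            expire = np.zeros(n_per, dtype=bool)
            if i > 0:  # one update per displayed frame after the first
                expire = rng.random(n_per) < params.realloc_prob
                pos = pos + vel
                outside = np.hypot(pos[:, 0], pos[:, 1]) > R
                realloc = expire | outside
                if realloc.any():
                    pos[realloc] = _uniform_disk(int(realloc.sum()), R, rng)
            frames_out.append(np.full(n_per, f))
            sets_out.append(np.full(n_per, s))
            dots_out.append(dot_ids + s * n_per)
            xs.append(pos[:, 0].copy())
            ys.append(pos[:, 1].copy())
            realloc_out.append(realloc)
            expired_out.append(expire)
    return pd.DataFrame(
        {
            "frame": np.concatenate(frames_out),
            "set": np.concatenate(sets_out),
            "dot": np.concatenate(dots_out),
            "x_cm": np.concatenate(xs),
            "y_cm": np.concatenate(ys),
            "reallocated": np.concatenate(realloc_out),
            "expired": np.concatenate(expired_out),
        }
    )
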
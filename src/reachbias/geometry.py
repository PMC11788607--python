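"""Screen geometry of the reaching task.

All coordinates are in centimetres in the screen frame used throughout the
experiment: x measured from the body midline (positive rightward), y from the
bottom of the screen (positive upward).  The motor-cost manipulation lives
entirely in this module: the two response buttons are placed asymmetrically so
that one requires a short reach (15.4 cm from the start button) and the other
a long reach (38.5 cm), with the near side swapping between the two
conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

CONDITIONS: Tuple[str, str] = ("left_closer", "right_closer")
SIDES: Tuple[str, str] = ("left", "right")


@dataclass(frozen=True)
class Point:
    """A position on the screen, in cm (x from body midline, y from screen bottom)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point coordinates must be finite, got ({self.x}, {self.y})")

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> Tuple[float, float]:
        return (self.x, self.y)


def _default_buttons() -> Dict[str, Dict[str, Point]]:
    return {
        "left_closer": {"left": Point(-12.5, 16.5), "right": Point(31.25, 30.0)},
        "right_closer": {"left": Point(-31.25, 30.0), "right": Point(12.5, 16.5)},
    }


@dataclass(frozen=True)
class Layout:
    """Geometry of start and response buttons plus acquisition metadata.

    ``screen_tilt_deg`` and ``viewing_distance_cm`` are recorded for
    completeness only; no 3D reach modelling is done.
    """

    start_center: Point = Point(0.0, 7.5)
    start_radius: float = 2.5
    button_radius: float = 1.7
    sample_rate: float = 60.0
    buttons: Mapping[str, Mapping[str, Point]] = field(default_factory=_default_buttons)
    screen_tilt_deg: float = 43.0
    viewing_distance_cm: float = 70.0

    def __post_init__(self) -> None:
        if self.start_radius <= 0 or self.button_radius <= 0:
            raise ValueError("button radii must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for cond in CONDITIONS:
            if cond not in self.buttons:
                raise ValueError(f"layout is missing button positions for {cond!r}")
            left, right = self.buttons[cond]["left"], self.buttons[cond]["right"]
            if not (left.x < 0 < right.x):
                raise ValueError(
                    f"{cond}: left button must be at x<0 and right at x>0, "
                    f"got x={left.x} and x={right.x}"
                )

    @property
    def dt_ms(self) -> float:
        """Inter-sample interval of the stylus trace, in ms."""
        return 1000.0 / self.sample_rate

    def to_dict(self) -> dict:
        return {
            "start_center": list(self.start_center.as_tuple()),
            "start_radius": self.start_radius,
            "button_radius": self.button_radius,
            "sample_rate": self.sample_rate,
            "buttons": {
                cond: {side: list(pt.as_tuple()) for side, pt in sides.items()}
                for cond, sides in self.buttons.items()
            },
            "screen_tilt_deg": self.screen_tilt_deg,
            "viewing_distance_cm": self.viewing_distance_cm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Layout":
        kwargs = dict(d)
        if "start_center" in kwargs:
            kwargs["start_center"] = Point(*kwargs["start_center"])
        if "buttons" in kwargs:
            kwargs["buttons"] = {
                cond: {side: Point(*xy) for side, xy in sides.items()}
                for cond, sides in kwargs["buttons"].items()
            }
        return cls(**kwargs)


DEFAULT_LAYOUT = Layout()


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; valid conditions are {CONDITIONS[0]!r} "
            f"and {CONDITIONS[1]!r}"
        )


def button_positions(condition: str, layout: Layout = DEFAULT_LAYOUT) -> Tuple[Point, Point]:
    """Centers of the (left, right) response buttons for a condition."""
    _check_condition(condition)
    sides = layout.buttons[condition]
    return sides["left"], sides["right"]


def reach_distance(a: Point, b: Point) -> float:
    """Euclidean distance between two screen points, in cm."""
    return a.distance_to(b)


def movement_angle(start: Point, target: Point) -> float:
    """Angle of the straight reach vector, in degrees CCW from +x, in (-180, 180]."""
    dx, dy = target.x - start.x, target.y - start.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("movement_angle is undefined for a zero-length reach")
    angle = math.degrees(math.atan2(dy, dx))
    if angle <= -180.0:  # atan2 returns (-180, 180]; keep the convention explicit
        angle += 360.0
    return angle


def near_side(condition: str) -> str:
    """Which side ('left'/'right') carries the short reach in a condition."""
    _check_condition(condition)
    return "left" if condition == "left_closer" else "right"


def far_side(condition: str) -> str:
    _check_condition(condition)
    return "right" if condition == "left_closer" else "left"


def is_near_choice(condition: str, choice: str) -> bool:
    """True if ``choice`` ('left'/'right') is the closer button in ``condition``."""
    if choice not in SIDES:
        raise ValueError(f"choice must be 'left' or 'right', got {choice!r}")
    return choice == near_side(condition)


def reach_distances(condition: str, layout: Layout = DEFAULT_LAYOUT) -> Dict[str, float]:
    """Start-to-button distances per side for one condition, in cm."""
    left, right = button_positions(condition, layout)
    return {
        "left": reach_distance(layout.start_center, left),
        "right": reach_distance(layout.start_center, right),
    }
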
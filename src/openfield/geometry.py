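"""Arena geometry and planar/angular helpers.

Coordinate conventions used throughout the package:

* the southwest corner of the arena is the origin ``(0, 0)``; x increases
  to the east and y to the north (units: cm);
* angles are measured in degrees counterclockwise from the positive
  x-axis (east = 0, north = 90) and wrapped to ``[0, 360)``;
* signed angular differences are wrapped to ``[-180, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CUE_WALLS = ("south", "east", "west", "north", "south+north")


def wrap_deg(angle) -> np.ndarray | float:
    """Wrap angle(s) into [0, 360)."""
    return np.mod(angle, 360.0)


def wrap_signed_deg(angle) -> np.ndarray | float:
    """Wrap angle(s) into [-180, 180)."""
    return np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0


def circdiff_deg(a, b):
    """Signed circular difference a - b in [-180, 180)."""
    return wrap_signed_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def rotate_about(points, center, angle_deg):
    """Rotate 2D point(s) about ``center`` by ``angle_deg`` counterclockwise."""
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, dtype=float)
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    out = p @ rot.T + np.asarray(center, dtype=float)
    return out[0] if np.ndim(points) == 1 else out


@dataclass(frozen=True)
class ArenaGeometry:
    """Square open-field arena with a goal zone and a wall-mounted cue card.

    The default geometry is a 120 x 120 cm box whose 15 cm square goal zone
    is centered 35 cm from the west wall and 45 cm from the north wall, with
    the cue card on the south wall.
    """

    side_length: float = 120.0
    goal_zone_center: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    goal_zone_side: float = 15.0
    cue_wall: str = "south"

    def __post_init__(self):
        if self.goal_zone_center is None:
            object.__setattr__(
                self,
                "goal_zone_center",
                (35.0, self.side_length - 45.0),
            )
        if self.cue_wall not in CUE_WALLS:
            raise ValueError(f"cue_wall must be one of {CUE_WALLS}, got {self.cue_wall!r}")
        cx, cy = self.goal_zone_center
        h = self.goal_zone_side / 2.0
        if not (0 <= cx - h and cx + h <= self.side_length and 0 <= cy - h and cy + h <= self.side_length):
            raise ValueError("goal zone must lie fully inside the arena")

    @property
    def center(self) -> tuple[float, float]:
        return (self.side_length / 2.0, self.side_length / 2.0)

    @property
    def goal_zone_bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the goal zone; membership is half-open [x0, x1) x [y0, y1)."""
        cx, cy = self.goal_zone_center
        h = self.goal_zone_side / 2.0
        return (cx - h, cy - h, cx + h, cy + h)

    def equivalent_zone_centers(self) -> list[tuple[float, float]]:
        """Goal-zone center and its 90/180/270-degree rotational images about the arena center."""
        return [
            tuple(rotate_about(np.array(self.goal_zone_center), self.center, a))
            for a in (0.0, 90.0, 180.0, 270.0)
        ]

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x <= self.side_length) & (y >= 0) & (y <= self.side_length)


def zone_membership(x, y, center, side) -> np.ndarray:
    """Boolean membership of points in a square zone, half-open bounds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = center
    h = side / 2.0
    return (x >= cx - h) & (x < cx + h) & (y >= cy - h) & (y < cy + h)
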
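"""Arena geometry, quadrant assignment, illumination schedule and light field.

The behavioral arena is a circular chamber (10 cm diameter by default) whose
floor is divided into four quadrants by two perpendicular borders fixed along
the coordinate axes, with the origin at the arena center and positions in mm.
Diagonally opposite quadrant pairs can be illuminated with activating red
light according to an epoch schedule; the light intensity ramps up linearly
over a short gradient on the lit side of each border.

Quadrant labels follow the sign pattern of (x, y):

    Q1 = (+, +)   Q2 = (-, +)   Q3 = (+, -)   Q4 = (-, -)

so that {Q2, Q3} and {Q1, Q4} are the two diagonal pairs that are lit
together. Points lying exactly on an axis are assigned deterministically by
treating the zero coordinate as positive (a strictly positive perturbation,
first in x then in y); border-distance ties choose the vertical-axis border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ArenaConfig",
    "Epoch",
    "IlluminationSchedule",
    "Trajectory",
    "OutOfArenaError",
    "QUADRANTS",
    "DIAGONAL_PAIRS",
    "assign_quadrant",
    "quadrant_codes",
    "border_distance",
    "in_choice_zone",
    "illumination_state",
    "light_intensity",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
DIAGONAL_PAIRS = (frozenset({"Q1", "Q4"}), frozenset({"Q2", "Q3"}))

VERTICAL = "vertical"  # the border line along the y-axis (x = 0)
HORIZONTAL = "horizontal"  # the border line along the x-axis (y = 0)


class OutOfArenaError(ValueError):
    """A position lies outside the arena beyond the allowed tolerance."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and illumination parameters of the circular arena.

    Parameters
    ----------
    radius
        Arena radius in mm (10 cm diameter arena -> 50 mm).
    choice_halfwidth
        Half-width of the choice zone band around each lit/unlit border, mm.
    center_exclusion_radius
        Radius of the central disk excluded from the choice zone, mm. The
        two borders intersect at the center (where the arena also has an air
        hole), making "which border" ill-defined there.
    frame_rate
        Video sampling rate, Hz.
    intensity_max
        Plateau irradiance on the lit side, µW/mm².
    intensity_min_at_border
        Irradiance at the lit/unlit border, µW/mm².
    gradient_length
        Length of the linear intensity ramp extending from the border, mm.
    bounds_tolerance
        Positions up to this far beyond ``radius`` are tolerated (tracker
        jitter); anything farther raises :class:`OutOfArenaError`.
    """

    radius: float = 50.0
    choice_halfwidth: float = 5.0
    center_exclusion_radius: float = 10.0
    frame_rate: float = 30.0
    intensity_max: float = 34.0
    intensity_min_at_border: float = 3.0
    gradient_length: float = 10.0
    bounds_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0 < self.choice_halfwidth < self.radius):
            raise ValueError("choice_halfwidth must be in (0, radius)")
        if self.center_exclusion_radius < self.choice_halfwidth:
            raise ValueError(
                "center_exclusion_radius must be >= choice_halfwidth"
            )
        if not (self.intensity_max >= self.intensity_min_at_border >= 0):
            raise ValueError(
                "need intensity_max >= intensity_min_at_border >= 0"
            )
        if self.gradient_length <= 0:
            raise ValueError("gradient_length must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


def _as_xy(point) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(point, dtype=float)
    if p.shape[-1] != 2:
        raise ValueError("point must have two coordinates (x, y)")
    return p[..., 0], p[..., 1]


def _check_bounds(x, y, config: ArenaConfig, context: str | None = None):
    r = np.hypot(x, y)
    bad = r > config.radius + config.bounds_tolerance
    if np.any(bad):
        where = f" ({context})" if context else ""
        rmax = float(np.max(r))
        raise OutOfArenaError(
            f"position {rmax:.2f} mm from center exceeds arena radius "
            f"{config.radius} mm + {config.bounds_tolerance} mm tolerance"
            f"{where}"
        )
    return r


def quadrant_codes(x, y) -> np.ndarray:
    """Vectorized quadrant assignment returning integer codes 1..4.

    Axis ties resolve by treating a zero coordinate as positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xpos = x >= 0
    ypos = y >= 0
    # (+,+)=1, (-,+)=2, (+,-)=3, (-,-)=4
    return np.where(
        xpos, np.where(ypos, 1, 3), np.where(ypos, 2, 4)
    ).astype(np.int8)


def assign_quadrant(point, config: ArenaConfig, *, context: str | None = None) -> str:
    """Assign an in-bounds point to one of Q1..Q4 by the sign pattern of (x, y)."""
    x, y = _as_xy(point)
    _check_bounds(x, y, config, context)
    code = quadrant_codes(x, y)
    return QUADRANTS[int(code) - 1]


def border_distance(point, config: ArenaConfig, *, context: str | None = None):
    """Unsigned distance to the nearest border diameter and which border it is.

    Returns ``(distance_mm, border_id)`` where ``border_id`` is ``"vertical"``
    (the line x = 0) or ``"horizontal"`` (the line y = 0). Distance to the
    vertical border is |x|, to the horizontal border |y|; ties choose the
    vertical border.
    """
    x, y = _as_xy(point)
    _check_bounds(x, y, config, context)
    ax, ay = abs(float(x)), abs(float(y))
    if ax <= ay:
        return ax, VERTICAL
    return ay, HORIZONTAL


def _in_zone_mask(x, y, config: ArenaConfig) -> np.ndarray:
    d = np.minimum(np.abs(x), np.abs(y))
    r = np.hypot(x, y)
    return (d <= config.choice_halfwidth) & (r >= config.center_exclusion_radius)


def in_choice_zone(point, config: ArenaConfig, *, context: str | None = None) -> bool:
    """True iff the point lies in the ±choice_halfwidth band around a border,
    outside the central exclusion disk."""
    x, y = _as_xy(point)
    _check_bounds(x, y, config, context)
    return bool(_in_zone_mask(x, y, config))


@dataclass(frozen=True)
class Epoch:
    """One illumination epoch: ``lit`` quadrants are illuminated on [t_start, t_end)."""

    t_start: float
    t_end: float
    lit: frozenset

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("epoch requires t_start < t_end")
        lit = frozenset(self.lit)
        object.__setattr__(self, "lit", lit)
        if lit and lit != frozenset(QUADRANTS) and lit not in DIAGONAL_PAIRS:
            raise ValueError(
                "lit quadrants must be empty, a diagonal pair, or all four; "
                f"got {sorted(lit)}"
            )


@dataclass(frozen=True)
class IlluminationSchedule:
    """Ordered, contiguous, non-overlapping illumination epochs."""

    epochs: tuple

    def __post_init__(self) -> None:
        epochs = tuple(
            e if isinstance(e, Epoch) else Epoch(e[0], e[1], frozenset(e[2]))
            for e in self.epochs
        )
        if not epochs:
            raise ValueError("schedule needs at least one epoch")
        for a, b in zip(epochs, epochs[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValueError("epochs must be contiguous and ordered")
        object.__setattr__(self, "epochs", epochs)

    @classmethod
    def default(cls) -> "IlluminationSchedule":
        """The standard 120 s protocol: dark, Q2&3 lit, dark, Q1&4 lit (30 s each)."""
        return cls(
            (
                Epoch(0.0, 30.0, frozenset()),
                Epoch(30.0, 60.0, frozenset({"Q2", "Q3"})),
                Epoch(60.0, 90.0, frozenset()),
                Epoch(90.0, 120.0, frozenset({"Q1", "Q4"})),
            )
        )

    @property
    def t_start(self) -> float:
        return self.epochs[0].t_start

    @property
    def t_end(self) -> float:
        return self.epochs[-1].t_end

    def epoch_index_at(self, t: float) -> int:
        if not (self.t_start <= t <= self.t_end):
            raise ValueError(
                f"t = {t} s outside schedule span [{self.t_start}, {self.t_end}] s"
            )
        for i, e in enumerate(self.epochs):
            if e.t_start <= t < e.t_end:
                return i
        return len(self.epochs) - 1  # t == t_end

    def epoch_at(self, t: float) -> Epoch:
        return self.epochs[self.epoch_index_at(t)]

    def lit_at(self, t: float) -> frozenset:
        return self.epoch_at(t).lit

    def light_on_epochs(self) -> tuple:
        return tuple(e for e in self.epochs if e.lit)


def illumination_state(point, t: float, schedule: IlluminationSchedule,
                       config: ArenaConfig, *, context: str | None = None) -> str:
    """Return ``"lit"`` or ``"unlit"`` for a point at time t."""
    q = assign_quadrant(point, config, context=context)
    return "lit" if q in schedule.lit_at(t) else "unlit"


def light_intensity(point, t: float, schedule: IlluminationSchedule,
                    config: ArenaConfig, *, context: str | None = None) -> float:
    """Irradiance (µW/mm²) at a point and time.

    Zero during dark epochs and on the unlit side. On the lit side the
    intensity ramps linearly from ``intensity_min_at_border`` at the border
    to ``intensity_max`` at ``gradient_length`` from the border, and is
    constant beyond the ramp.
    """
    if illumination_state(point, t, schedule, config, context=context) == "unlit":
        return 0.0
    d, _ = border_distance(point, config, context=context)
    lo = config.intensity_min_at_border
    hi = config.intensity_max
    frac = min(d, config.gradient_length) / config.gradient_length
    return lo + (hi - lo) * frac


@dataclass
class Trajectory:
    """Time-ordered positions of a single fly in arena coordinates (mm).

    Frames must be strictly increasing; gaps (missing frames) are allowed and
    are handled downstream (they censor choice-zone events and break
    kinematics differences).
    """

    fly_id: str
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frame)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise ValueError(f"fly {self.fly_id}: sample arrays differ in length")
        if n == 0:
            raise ValueError(f"fly {self.fly_id}: empty trajectory")
        d = np.diff(self.frame)
        if np.any(d <= 0):
            bad = int(self.frame[1:][d <= 0][0])
            raise ValueError(
                f"fly {self.fly_id}: frames not strictly increasing at frame {bad}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def validate_bounds(self, config: ArenaConfig) -> None:
        r = np.hypot(self.x, self.y)
        bad = r > config.radius + config.bounds_tolerance
        if np.any(bad):
            i = int(np.argmax(bad))
            raise OutOfArenaError(
                f"fly {self.fly_id} frame {int(self.frame[i])}: position "
                f"({self.x[i]:.2f}, {self.y[i]:.2f}) mm is outside the arena "
                f"(radius {config.radius} mm + {config.bounds_tolerance} mm tolerance)"
            )

    @classmethod
    def from_positions(cls, fly_id, x, y, config: ArenaConfig,
                       frame_start: int = 0) -> "Trajectory":
        """Build a gap-free trajectory from consecutive positions at the
        configured frame rate."""
        x = np.asarray(x, dtype=float)
        frames = frame_start + np.arange(len(x), dtype=np.int64)
        return cls(fly_id=str(fly_id), frame=frames,
                   t=frames / config.frame_rate, x=x, y=np.asarray(y, dtype=float))
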
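"""Synthetic data generators with the statistical structure the analyses assume.

Three generators exercise the whole pipeline without recorded data:

* ``simulate_arena_cohort`` — a cohort of correlated-random-walk agents in
  the quadrant arena. Each fly draws a per-frame speed from a truncated
  normal, diffuses its heading, and steers smoothly away from the wall.
  Behavioral valence acts only at choice-zone entries: entering while
  heading toward the lit side, a fly executes a smooth ~180° reversal with
  probability max(0, -valence); heading toward the dark side, with
  probability max(0, +valence). In the complementary favorable case the fly
  commits to crossing with probability |valence| (heading diffusion is
  suppressed until it leaves the zone), so the expected exit-to-lit
  fraction is strictly monotone in valence on both sides of zero. Optional
  lit-quadrant multipliers scale speed and heading diffusion to emulate
  kinematic (sensory-neuron-style) phenotypes; by default they are 1, so
  valence biases border choice without touching steady-state kinematics.
* ``simulate_dam`` — per-minute wake/sleep two-state Markov chains with
  phase- and light-dependent transition probabilities; beam counts are
  Poisson while awake and zero while asleep. An activation-phase factor
  rescales the stationary sleep probability to impose a target sleep change.
* ``simulate_tmaze`` — reciprocal two-group binomial choices with an innate
  arm bias b and a learning effect δ: each fly picks the bias-favored arm
  with probability 0.5 + b/2 ± δ/2, the sign of the δ term set by the
  group's CS+ assignment.

Identical seeds reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .arena import ArenaConfig, IlluminationSchedule, Trajectory, quadrant_codes
from .memory import GroupCounts, ReciprocalExperiment
from .sleep import ActivityRecord, DEFAULT_PHASES, MINUTES_PER_DAY

__all__ = [
    "AgentParams",
    "DamParams",
    "TmazeParams",
    "combine_valences",
    "simulate_arena_cohort",
    "simulate_dam",
    "simulate_tmaze",
]


def combine_valences(*valences: float) -> float:
    """Co-activation rule: valences add and saturate at ±1."""
    return float(np.clip(sum(valences), -1.0, 1.0))


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the correlated-random-walk arena cohort.

    Defaults emulate the standard cohort: ~20 flies, 120 s protocol at
    30 fps. ``mean_speed``/``speed_sd`` (mm/s) set the walking-speed
    distribution; ``heading_diffusion`` (deg²/s) the heading random walk;
    ``wall_avoidance_range`` (mm) the smooth border-avoidance band.
    ``valence`` in [-1, 1] biases choice-zone exits (negative =
    light-aversive); the lit multipliers scale speed and heading diffusion
    in illuminated quadrants.
    """

    n_flies: int = 20
    duration: float = 120.0
    frame_rate: float = 30.0
    mean_speed: float = 10.0
    speed_sd: float = 3.0
    heading_diffusion: float = 3000.0
    wall_avoidance_range: float = 8.0
    valence: float = 0.0
    lit_speed_multiplier: float = 1.0
    lit_turn_multiplier: float = 1.0
    reversal_duration_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if abs(self.valence) > 1:
            raise ValueError("valence must lie in [-1, 1]")
        if self.lit_speed_multiplier <= 0 or self.lit_turn_multiplier <= 0:
            raise ValueError("lit multipliers must be positive")
        if self.mean_speed <= 0 or self.speed_sd < 0:
            raise ValueError("mean_speed must be > 0 and speed_sd >= 0")
        if self.heading_diffusion < 0 or self.wall_avoidance_range <= 0:
            raise ValueError(
                "heading_diffusion must be >= 0, wall_avoidance_range > 0"
            )


def _wrap_pi(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def simulate_arena_cohort(
    params: AgentParams,
    config: Optional[ArenaConfig] = None,
    schedule: Optional[IlluminationSchedule] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Trajectory]:
    """Simulate one cohort (one video) and return per-fly trajectories."""
    config = config or ArenaConfig(frame_rate=params.frame_rate)
    schedule = schedule or IlluminationSchedule.default()
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    n = params.n_flies
    fps = params.frame_rate
    dt = 1.0 / fps
    n_frames = int(round(params.duration * fps))
    R = config.radius
    n_rev = max(1, int(round(params.reversal_duration_s * fps)))

    # quadrant lit lookup per frame: lit_lut[frame, code] for codes 1..4
    lit_lut = np.zeros((n_frames, 5), dtype=bool)
    for k in range(n_frames):
        lit = schedule.lit_at(min(k * dt, schedule.t_end))
        for q in lit:
            lit_lut[k, int(q[1])] = True

    # initial state: uniform over the disk (slightly inside the wall band)
    r0 = (R - 2.0) * np.sqrt(rng.random(n))
    th0 = rng.uniform(-np.pi, np.pi, n)
    x = r0 * np.cos(th0)
    y = r0 * np.sin(th0)
    heading = rng.uniform(-np.pi, np.pi, n)

    FREE, REVERSING, COMMITTED = 0, 1, 2
    mode = np.full(n, FREE, dtype=np.int8)
    rev_left = np.zeros(n, dtype=np.int64)
    rev_step = np.zeros(n)
    decided = np.zeros(n, dtype=bool)  # one decision per zone visit
    prev_in_zone = np.zeros(n, dtype=bool)

    X = np.empty((n_frames, n))
    Y = np.empty((n_frames, n))

    sigma0 = np.sqrt(params.heading_diffusion * dt) * np.pi / 180.0
    half = config.choice_halfwidth
    excl = config.center_exclusion_radius
    v = params.valence

    for k in range(n_frames):
        X[k] = x
        Y[k] = y

        codes = quadrant_codes(x, y)
        is_lit = lit_lut[k][codes]
        in_zone = (np.minimum(np.abs(x), np.abs(y)) <= half) & (
            np.hypot(x, y) >= excl
        )

        exited = prev_in_zone & ~in_zone
        decided[exited] = False
        mode[exited & (mode == COMMITTED)] = FREE

        entered = in_zone & ~prev_in_zone
        epoch_lit = lit_lut[k].any()
        cand = entered & ~decided & (mode == FREE)
        if epoch_lit and np.any(cand):
            # heading toward lit iff currently on the unlit side
            toward_lit = ~is_lit
            p_rev = np.where(toward_lit, max(0.0, -v), max(0.0, v))
            p_commit = np.where(toward_lit, max(0.0, v), max(0.0, -v))
            u1 = rng.random(n)
            u2 = rng.random(n)
            rev = cand & (u1 < p_rev)
            commit = cand & ~rev & (u2 < p_commit)
            mode[rev] = REVERSING
            rev_left[rev] = n_rev
            sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            jitter = rng.normal(0.0, 0.3, n)
            rev_step[rev] = (sign * (np.pi + jitter) / n_rev)[rev]
            mode[commit] = COMMITTED
            if np.any(commit):
                # a committed fly aims across its nearest border (jittered),
                # guaranteeing the crossing the commitment represents
                near_vertical = np.abs(x) <= np.abs(y)
                cross_heading = np.where(
                    near_vertical,
                    np.where(x < 0, 0.0, np.pi),
                    np.where(y < 0, np.pi / 2, -np.pi / 2),
                )
                cross_heading = cross_heading + rng.normal(0.0, 0.35, n)
                heading = np.where(commit, cross_heading, heading)
        decided[entered] = True
        prev_in_zone = in_zone

        # heading diffusion (free walkers only)
        sigma = np.where(
            is_lit, sigma0 * np.sqrt(params.lit_turn_multiplier), sigma0
        )
        dh = rng.normal(0.0, 1.0, n) * sigma
        dh[mode != FREE] = 0.0
        heading = heading + dh

        reversing = mode == REVERSING
        heading[reversing] += rev_step[reversing]
        rev_left[reversing] -= 1
        mode[reversing & (rev_left <= 0)] = FREE

        # smooth wall avoidance: steer toward the center inside the band
        r = np.hypot(x, y)
        near = (r > R - params.wall_avoidance_range) & (mode == FREE)
        if np.any(near):
            inward = np.arctan2(-y, -x)
            closeness = np.clip(
                (r - (R - params.wall_avoidance_range))
                / params.wall_avoidance_range,
                0.0,
                1.0,
            )
            gain = 0.4 * closeness**2
            delta = _wrap_pi(inward - heading)
            heading = np.where(near, heading + gain * delta, heading)

        speed = np.clip(rng.normal(params.mean_speed, params.speed_sd, n), 0.0, None)
        speed = np.where(is_lit, speed * params.lit_speed_multiplier, speed)

        step = speed * dt
        nx = x + step * np.cos(heading)
        ny = y + step * np.sin(heading)
        out = np.hypot(nx, ny) > R
        if np.any(out):
            # slide along the wall: rotate about the arena center by the arc
            # the step length subtends, so the radius never grows and the
            # measured per-frame displacement stays ~step (no speed artifact
            # from wall contact)
            r_cur = np.maximum(np.hypot(x, y), 1e-9)
            txh, tyh = -y / r_cur, x / r_cur  # CCW tangent at current position
            vx, vy = np.cos(heading), np.sin(heading)
            sgn = np.where(vx * txh + vy * tyh >= 0, 1.0, -1.0)
            phi = sgn * step / r_cur
            c, s = np.cos(phi), np.sin(phi)
            rx = c * x - s * y
            ry = s * x + c * y
            nx = np.where(out, rx, nx)
            ny = np.where(out, ry, ny)
            # heading follows the rotated tangent, in the travel direction
            ttx = c * txh - s * tyh
            tty = s * txh + c * tyh
            heading = np.where(out, np.arctan2(sgn * tty, sgn * ttx), heading)
        x, y = nx, ny

    return [
        Trajectory.from_positions(f"fly{j:02d}", X[:, j], Y[:, j], config)
        for j in range(n)
    ]


@dataclass(frozen=True)
class DamParams:
    """Parameters of the wake/sleep Markov-chain activity generator.

    Transition probabilities are per minute and depend on the light period;
    defaults give realistic baseline sleep (~660 min/day, night-heavy, mean
    bout lengths ~12 min by day and ~20 min by night, which also keeps the
    sampling variance of single-day sleep totals moderate so cohort-level
    effects are well resolved at n = 32). ``activation_sleep_factor``
    rescales the
    stationary sleep probability during the activation phase (0.6 imposes a
    -40% sleep change) while keeping sleep-bout lengths unchanged, so the
    >= 5-min scoring criterion affects all phases equally.
    """

    n_channels: int = 32
    n_days: int = 7
    phases: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_PHASES)
    )
    p_wake_to_sleep: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.03, "dark": 0.09}
    )
    p_sleep_to_wake: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.08, "dark": 0.05}
    )
    activation_sleep_factor: float = 1.0
    mean_waking_counts: float = 2.0
    light_minutes: int = 720
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.p_wake_to_sleep, self.p_sleep_to_wake):
            for key in ("light", "dark"):
                if not (0.0 < m[key] < 1.0):
                    raise ValueError("transition probabilities must lie in (0, 1)")
        if self.mean_waking_counts < 0:
            raise ValueError("mean_waking_counts must be >= 0")
        if self.n_channels < 1 or self.n_days < 1:
            raise ValueError("n_channels and n_days must be >= 1")
        if self.activation_sleep_factor <= 0:
            raise ValueError("activation_sleep_factor must be positive")
        missing = [d for d in range(1, self.n_days + 1) if d not in self.phases]
        if missing:
            raise ValueError(f"days {missing} lack a phase label")

    @classmethod
    def with_sleep_change(cls, percent: float, **kwargs) -> "DamParams":
        """Parameters whose activation phase imposes the given expected
        percent sleep change (e.g. -40 for a 40% reduction)."""
        return cls(activation_sleep_factor=1.0 + percent / 100.0, **kwargs)

    def transition_probs(self, phase: str, light: str) -> tuple[float, float]:
        """(wake->sleep, sleep->wake) per-minute probabilities."""
        a = self.p_wake_to_sleep[light]
        b = self.p_sleep_to_wake[light]
        if phase == "activation" and self.activation_sleep_factor != 1.0:
            f = self.activation_sleep_factor
            # rescale the stationary sleep probability pi = a/(a+b) by f,
            # keeping b (hence the bout-length distribution) fixed
            denom = a + b - f * a
            if denom <= 0:
                raise ValueError(
                    "activation_sleep_factor too large for these probabilities"
                )
            a = f * a * b / denom
            a = min(max(a, 1e-9), 1.0 - 1e-9)
        return a, b

    def stationary_sleep_prob(self, phase: str, light: str) -> float:
        a, b = self.transition_probs(phase, light)
        return a / (a + b)


def simulate_dam(
    params: DamParams,
    rng: Optional[np.random.Generator] = None,
) -> list[ActivityRecord]:
    """Simulate DAM channels and return per-fly activity records."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_channels
    total = params.n_days * MINUTES_PER_DAY
    counts = np.zeros((total, n), dtype=np.int64)

    # start each fly from the stationary distribution of day 1, lights-on
    phase0 = params.phases[1]
    asleep = rng.random(n) < params.stationary_sleep_prob(phase0, "light")

    for minute in range(total):
        day = minute // MINUTES_PER_DAY + 1
        light = "light" if minute % MINUTES_PER_DAY < params.light_minutes else "dark"
        a, b = params.transition_probs(params.phases[day], light)
        u = rng.random(n)
        fall = ~asleep & (u < a)
        wake = asleep & (u < b)
        asleep = (asleep & ~wake) | fall
        awake = ~asleep
        if np.any(awake):
            c = rng.poisson(params.mean_waking_counts, n)
            counts[minute, awake] = c[awake]

    return [
        ActivityRecord(
            channel=f"ch{j + 1:02d}",
            counts=counts[:, j],
            phases=dict(params.phases),
            light_minutes=params.light_minutes,
        )
        for j in range(n)
    ]


@dataclass(frozen=True)
class TmazeParams:
    """Reciprocal T-maze generator: innate arm bias ``bias`` toward the
    first odor and learning effect ``delta`` (expected PI)."""

    n_flies: int = 50
    bias: float = 0.0
    delta: float = 0.0
    odors: tuple[str, str] = ("OCT", "MCH")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if abs(self.bias) + abs(self.delta) > 1.0:
            raise ValueError("|bias| + |delta| must be <= 1")


def simulate_tmaze(
    params: TmazeParams,
    rng: Optional[np.random.Generator] = None,
) -> ReciprocalExperiment:
    """Simulate one reciprocal experiment (punishment-style training).

    Group 1 is trained with the first odor as CS+, group 2 with the second.
    Each fly chooses the first odor with probability 0.5 + bias/2 - delta/2
    (group 1: trained to avoid it) or 0.5 + bias/2 + delta/2 (group 2).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    odor_a, odor_b = params.odors
    p1 = 0.5 + params.bias / 2.0 - params.delta / 2.0
    p2 = 0.5 + params.bias / 2.0 + params.delta / 2.0
    n = params.n_flies
    k1 = int(rng.binomial(n, np.clip(p1, 0.0, 1.0)))
    k2 = int(rng.binomial(n, np.clip(p2, 0.0, 1.0)))
    group1 = GroupCounts(cs_plus=odor_a, counts={odor_a: k1, odor_b: n - k1})
    group2 = GroupCounts(cs_plus=odor_b, counts={odor_a: k2, odor_b: n - k2})
    return ReciprocalExperiment(group1=group1, group2=group2,
                                modality="olfactory_tmaze")
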
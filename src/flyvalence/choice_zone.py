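"""Choice-zone visit segmentation, exit classification and kinematics.

A "choice zone" is the ±5 mm band around the border between a lit and an
unlit quadrant. Each visit by a fly (entering from outside the band and
later leaving it) is one choice event. Events are classified by where the
fly exits: a *crossing* exits to the opposite illumination state from the
one it entered from, a *turnaround* exits back to the same state. Events are
filtered by entry angle (45-135°, i.e. roughly facing the border) and by
prior movement (net displacement > 5 mm in the 1 s before entry) so that
only committed, walking approaches are scored. The *choice probability* of
a cohort is the fraction of retained events exiting to the lit side,
irrespective of entry side.

Speed is the frame-to-frame displacement times the frame rate; angular
speed is the absolute frame-to-frame change in the velocity heading (the
heading of the displacement vector) times the frame rate, wrapped to
[0, 180°] per frame. Headings are undefined below a small speed threshold,
where displacement direction is dominated by tracker jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .arena import (
    ArenaConfig,
    IlluminationSchedule,
    Trajectory,
    VERTICAL,
    HORIZONTAL,
    _in_zone_mask,
    quadrant_codes,
)

__all__ = [
    "ChoiceEvent",
    "segment_choice_events",
    "entry_angle",
    "filter_events",
    "exit_fractions",
    "choice_probability",
    "kinematics",
    "state_conditioned_kinematics",
]

CROSSING = "crossing"
TURNAROUND = "turnaround"
CENSORED = "censored"


@dataclass
class ChoiceEvent:
    """One choice-zone visit by one fly."""

    fly_id: str
    t_entry: float
    frame_entry: int
    entry_border: str
    entry_side: Optional[str]  # "lit" | "unlit" | None when censored in the dark
    entry_angle: Optional[float] = None  # degrees in [0, 180); None if unfilterable
    prior_displacement: Optional[float] = None  # mm over the 1 s before entry
    t_exit: Optional[float] = None
    exit_side: str = CENSORED  # "lit" | "unlit" | "censored"
    outcome: str = CENSORED  # "crossing" | "turnaround" | "censored"
    censor_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.entry_angle is not None and not (0 <= self.entry_angle <= 180):
            raise ValueError("entry_angle must lie in [0, 180]")
        if self.prior_displacement is not None and self.prior_displacement < 0:
            raise ValueError("prior_displacement must be non-negative")
        if self.outcome == CROSSING and self.exit_side == self.entry_side:
            raise ValueError("a crossing must exit to the opposite side")
        if self.outcome == TURNAROUND and self.exit_side != self.entry_side:
            raise ValueError("a turnaround must exit to the entry side")


def _lit_state(code: int, lit: frozenset) -> str:
    return "lit" if f"Q{code}" in lit else "unlit"


def entry_angle_from_samples(dx: float, dy: float, border: str) -> Optional[float]:
    """Angle between a heading vector and a border line, folded to [0, 180).

    Parallel approach -> 0 (or ~180), perpendicular -> 90. Returns None for a
    zero-length heading vector.
    """
    if dx == 0 and dy == 0:
        return None
    heading = np.degrees(np.arctan2(dy, dx))
    border_angle = 90.0 if border == VERTICAL else 0.0
    return float((heading - border_angle) % 180.0)


def entry_angle(trajectory: Trajectory, event: ChoiceEvent,
                config: ArenaConfig, window_frames: int = 3) -> Optional[float]:
    """Entry angle of an event: heading from ``window_frames`` before entry
    to the entry frame, measured against the entry border line.

    Returns None (the event is unfilterable) when the pre-entry window is
    missing or interrupted by a tracking gap.
    """
    idx = np.searchsorted(trajectory.frame, event.frame_entry)
    if idx >= len(trajectory) or trajectory.frame[idx] != event.frame_entry:
        raise ValueError(
            f"event entry frame {event.frame_entry} not in trajectory "
            f"{trajectory.fly_id}"
        )
    j = idx - window_frames
    if j < 0 or trajectory.frame[j] != event.frame_entry - window_frames:
        return None
    dx = trajectory.x[idx] - trajectory.x[j]
    dy = trajectory.y[idx] - trajectory.y[j]
    return entry_angle_from_samples(dx, dy, event.entry_border)


def _prior_displacement(trajectory: Trajectory, idx_entry: int,
                        config: ArenaConfig, mode: str = "net") -> Optional[float]:
    """Displacement over the 1 s before entry; ``mode`` is "net" (default)
    or "path" (summed frame-to-frame path length over a gap-free second)."""
    back = int(round(config.frame_rate))
    target = trajectory.frame[idx_entry] - back
    j = np.searchsorted(trajectory.frame, target)
    if j >= len(trajectory) or trajectory.frame[j] != target:
        return None
    if mode == "net":
        return float(np.hypot(trajectory.x[idx_entry] - trajectory.x[j],
                              trajectory.y[idx_entry] - trajectory.y[j]))
    if mode == "path":
        fr = trajectory.frame[j:idx_entry + 1]
        if np.any(np.diff(fr) != 1):
            return None
        dx = np.diff(trajectory.x[j:idx_entry + 1])
        dy = np.diff(trajectory.y[j:idx_entry + 1])
        return float(np.sum(np.hypot(dx, dy)))
    raise ValueError("mode must be 'net' or 'path'")


def segment_choice_events(
    trajectory: Trajectory,
    config: ArenaConfig,
    schedule: IlluminationSchedule,
    *,
    heading_window_frames: int = 3,
    prior_mode: str = "net",
    settle_s: float = 1.0,
) -> tuple[list[ChoiceEvent], dict]:
    """Segment one fly's trajectory into choice-zone events.

    An event opens at the first sample inside the zone band after a sample
    outside it, and closes at the first subsequent sample outside the band.
    Events are censored (outcome "censored") when they end at track loss,
    contain a tracking gap, straddle an illumination-epoch boundary, occur
    in a dark epoch (no lit quadrants: entry side undefined), or start
    within ``settle_s`` of a light-on transition.

    Returns ``(events, info)`` where ``info`` counts samples and censoring
    reasons; ``info["always_inside"]`` flags a trajectory that never leaves
    the band (zero events).
    """
    trajectory.validate_bounds(config)
    tr = trajectory
    inside = _in_zone_mask(tr.x, tr.y, config)
    n = len(tr)
    info = {
        "n_events": 0,
        "n_censored": 0,
        "censor_reasons": {},
        "always_inside": bool(inside.all()) and n > 0,
        "starts_inside_skipped": 0,
    }

    def _censor(reason: str) -> None:
        info["n_censored"] += 1
        info["censor_reasons"][reason] = info["censor_reasons"].get(reason, 0) + 1

    events: list[ChoiceEvent] = []
    i = 0
    # skip a leading in-zone stretch: no well-defined entry
    while i < n and inside[i]:
        i += 1
    if i > 0:
        info["starts_inside_skipped"] = 1
    while i < n:
        if not inside[i]:
            i += 1
            continue
        # entry at sample i, pre-entry sample i-1 (outside the band)
        pre = i - 1
        contiguous_entry = tr.frame[i] == tr.frame[pre] + 1
        # scan to the first sample outside the band
        j = i
        gap = not contiguous_entry
        while j < n and inside[j]:
            if j > i and tr.frame[j] != tr.frame[j - 1] + 1:
                gap = True
            j += 1
        lost = j >= n
        if not lost and tr.frame[j] != tr.frame[j - 1] + 1:
            gap = True

        t_entry = float(tr.t[i])
        ax, ay = abs(tr.x[i]), abs(tr.y[i])
        border = VERTICAL if ax <= ay else HORIZONTAL

        epoch_entry = schedule.epoch_at(float(tr.t[pre]))
        reason = None
        if gap:
            reason = "tracking_gap"
        elif lost:
            reason = "track_loss"
        elif not epoch_entry.lit:
            reason = "dark_epoch"
        elif schedule.epoch_at(float(tr.t[j])) is not epoch_entry:
            reason = "epoch_boundary"
        elif t_entry - epoch_entry.t_start < settle_s:
            reason = "epoch_settle"
        elif np.hypot(tr.x[pre], tr.y[pre]) < config.center_exclusion_radius:
            # the fly emerged from the central ambiguity disk: its entry side
            # is not a well-defined side of one border
            reason = "center_entry"
        elif np.hypot(tr.x[j], tr.y[j]) < config.center_exclusion_radius:
            # the visit ended in the central disk, not on a side of the border
            reason = "center_exit"

        entry_side = None
        if epoch_entry.lit:
            code = int(quadrant_codes(tr.x[pre], tr.y[pre]))
            entry_side = _lit_state(code, epoch_entry.lit)

        event = ChoiceEvent(
            fly_id=tr.fly_id,
            t_entry=t_entry,
            frame_entry=int(tr.frame[i]),
            entry_border=border,
            entry_side=entry_side,
        )
        if reason is None:
            code_exit = int(quadrant_codes(tr.x[j], tr.y[j]))
            exit_side = _lit_state(code_exit, epoch_entry.lit)
            event.t_exit = float(tr.t[j])
            event.exit_side = exit_side
            event.outcome = CROSSING if exit_side != entry_side else TURNAROUND
            event.entry_angle = entry_angle(
                tr, event, config, window_frames=heading_window_frames
            )
            event.prior_displacement = _prior_displacement(
                tr, i, config, mode=prior_mode
            )
        else:
            event.censor_reason = reason
            _censor(reason)
        events.append(event)
        info["n_events"] += 1
        i = j
    return events, info


def filter_events(
    events: Iterable[ChoiceEvent],
    *,
    angle_min: float = 45.0,
    angle_max: float = 135.0,
    min_prior_mm: float = 5.0,
) -> tuple[list[ChoiceEvent], dict]:
    """Apply the entry filters: keep events with entry angle in
    [angle_min, angle_max], prior displacement strictly greater than
    ``min_prior_mm`` and a non-censored outcome.

    Returns ``(kept, counts)`` where ``counts`` reports how many events each
    criterion removed (an event missing its angle or prior displacement is
    unfilterable and dropped).
    """
    events = list(events)
    counts = {
        "n_input": len(events),
        "censored": 0,
        "unfilterable": 0,
        "angle_rejected": 0,
        "prior_rejected": 0,
        "kept": 0,
    }
    kept: list[ChoiceEvent] = []
    for ev in events:
        if ev.outcome == CENSORED:
            counts["censored"] += 1
            continue
        if ev.entry_angle is None or ev.prior_displacement is None:
            counts["unfilterable"] += 1
            continue
        if not (angle_min <= ev.entry_angle <= angle_max):
            counts["angle_rejected"] += 1
            continue
        if not ev.prior_displacement > min_prior_mm:
            counts["prior_rejected"] += 1
            continue
        kept.append(ev)
    counts["kept"] = len(kept)
    return kept, counts


def exit_fractions(events: Iterable[ChoiceEvent]) -> dict:
    """Per-entry-side fraction of events exiting to the lit side, with
    Wilson 95% confidence intervals and raw counts.

    A side with zero retained events is reported as None.
    """
    events = list(events)
    out = {}
    for side in ("unlit", "lit"):
        sel = [ev for ev in events if ev.entry_side == side]
        n = len(sel)
        if n == 0:
            out[side] = None
            continue
        k = sum(1 for ev in sel if ev.exit_side == "lit")
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        out[side] = {
            "n": n,
            "n_exit_lit": k,
            "fraction_exit_lit": k / n,
            "ci95": (float(lo), float(hi)),
        }
    return out


def choice_probability(events: Iterable[ChoiceEvent]) -> float:
    """Fraction of retained events exiting to the lit side, irrespective of
    entry side."""
    events = list(events)
    if not events:
        raise ValueError("choice_probability requires at least one event")
    k = sum(1 for ev in events if ev.exit_side == "lit")
    return k / len(events)


def kinematics(trajectory: Trajectory, config: ArenaConfig,
               min_heading_speed: float = 0.5) -> pd.DataFrame:
    """Per-frame speed (mm/s) and angular speed (deg/s) of one fly.

    Both are frame-difference estimates at the configured frame rate. Values
    are NaN at the first sample, after tracking gaps, and (for angular
    speed) wherever either flanking displacement is below
    ``min_heading_speed`` mm/s, where the velocity heading is ill-posed.
    """
    tr = trajectory
    if len(tr) < 3:
        raise ValueError("kinematics needs at least 3 frames")
    fps = config.frame_rate
    contig = np.concatenate([[False], np.diff(tr.frame) == 1])
    dx = np.concatenate([[np.nan], np.diff(tr.x)])
    dy = np.concatenate([[np.nan], np.diff(tr.y)])
    speed = np.hypot(dx, dy) * fps
    speed[~contig] = np.nan

    heading = np.degrees(np.arctan2(dy, dx))
    heading[~contig | (speed < min_heading_speed)] = np.nan

    dh = np.abs(heading - np.concatenate([[np.nan], heading[:-1]]))
    dh = np.where(dh > 180.0, 360.0 - dh, dh)
    ang = dh * fps
    ang[~contig] = np.nan

    return pd.DataFrame(
        {"t_s": tr.t, "speed": speed, "angular_speed": ang},
        index=pd.Index(tr.frame, name="frame"),
    )


def state_conditioned_kinematics(
    trajectories: Sequence[Trajectory],
    schedule: IlluminationSchedule,
    config: ArenaConfig,
    min_heading_speed: float = 0.5,
) -> dict:
    """Mean speed and angular speed by quadrant illumination state, pooled
    over flies and restricted to light-on epochs, for one video.

    Returns lit/unlit means, the lit-minus-unlit changes and frame counts;
    a state never occupied yields NaN means.
    """
    speeds = {"lit": [], "unlit": []}
    angs = {"lit": [], "unlit": []}
    for tr in trajectories:
        kin = kinematics(tr, config, min_heading_speed=min_heading_speed)
        codes = quadrant_codes(tr.x, tr.y)
        for epoch in schedule.light_on_epochs():
            lit_codes = {int(q[1]) for q in epoch.lit}
            in_epoch = (tr.t >= epoch.t_start) & (tr.t < epoch.t_end)
            is_lit = np.isin(codes, list(lit_codes))
            # attribute a frame's speed to a state only when the whole
            # displacement lies within it: the boundary-crossing step itself
            # is size-biased (fast steps cross) and would contaminate the
            # rare state's mean
            same_prev = np.concatenate([[False], is_lit[1:] == is_lit[:-1]])
            same_prev2 = np.concatenate([[False], same_prev[:-1]]) & same_prev
            for state, mask in (("lit", is_lit), ("unlit", ~is_lit)):
                sel = in_epoch & mask & same_prev
                speeds[state].append(kin["speed"].to_numpy()[sel])
                sel_a = in_epoch & mask & same_prev2
                angs[state].append(kin["angular_speed"].to_numpy()[sel_a])

    out = {}
    for state in ("lit", "unlit"):
        sp = np.concatenate(speeds[state]) if speeds[state] else np.array([])
        an = np.concatenate(angs[state]) if angs[state] else np.array([])
        sp = sp[~np.isnan(sp)]
        an = an[~np.isnan(an)]
        out[f"speed_{state}"] = float(np.mean(sp)) if sp.size else float("nan")
        out[f"angular_{state}"] = float(np.mean(an)) if an.size else float("nan")
        out[f"n_frames_{state}"] = int(sp.size)
    out["speed_change"] = out["speed_lit"] - out["speed_unlit"]
    out["angular_change"] = out["angular_lit"] - out["angular_unlit"]
    return out
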
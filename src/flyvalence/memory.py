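"""Reciprocal-design performance indices for conditioning tests.

Associative conditioning experiments train two groups with swapped CS+/CS-
assignments (the reciprocal design) and average their preference indices so
that any innate stimulus bias, being identical in the two groups, cancels
exactly. Throughout this module the sign convention is standardized so that
a positive performance index (PI) always means behavior consistent with
training: avoiding the CS+ after punishment, approaching the CS+ after
reward. All indices lie in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupCounts",
    "ReciprocalExperiment",
    "tmaze_pi",
    "tmaze_test_series",
    "visual_pi",
    "ymaze_pi",
]

Reinforcement = Literal["punishment", "reward"]


@dataclass(frozen=True)
class GroupCounts:
    """Test-phase choice counts for one trained group.

    ``counts`` maps the two choice-option labels (odor names, colors) to fly
    counts; ``cs_plus`` names the option that was paired with reinforcement
    for this group.
    """

    cs_plus: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.cs_plus not in self.counts:
            raise ValueError(
                f"cs_plus {self.cs_plus!r} not among options {sorted(self.counts)}"
            )
        if len(self.counts) != 2:
            raise ValueError("expected exactly two choice options")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.counts.values()) == 0:
            raise ValueError("group has zero total flies")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def index(self, reinforcement: Reinforcement = "punishment") -> float:
        """Signed per-group preference index; positive = consistent with
        training."""
        n_plus = self.counts[self.cs_plus]
        n_minus = self.total - n_plus
        raw = (n_minus - n_plus) / self.total  # avoidance of CS+
        return raw if reinforcement == "punishment" else -raw


@dataclass(frozen=True)
class ReciprocalExperiment:
    """A reciprocally trained pair of groups tested on the same two options."""

    group1: GroupCounts
    group2: GroupCounts
    modality: str = "olfactory_tmaze"

    def __post_init__(self) -> None:
        if set(self.group1.counts) != set(self.group2.counts):
            raise ValueError("groups must share the same two options")
        if self.group1.cs_plus == self.group2.cs_plus:
            raise ValueError(
                "a reciprocal design needs swapped CS+ assignments between groups"
            )


def _reciprocal_mean(i1: float, i2: float) -> float:
    return float((i1 + i2) / 2.0)


def tmaze_pi(exp: ReciprocalExperiment,
             reinforcement: Reinforcement = "punishment") -> dict:
    """Performance index of a two-odor T-maze test.

    Each group's index is the normalized count difference between its CS-
    and CS+ arms (sign per the module convention); the PI is the mean of the
    two reciprocal indices.
    """
    if exp.modality != "olfactory_tmaze":
        raise ValueError(f"expected olfactory_tmaze data, got {exp.modality!r}")
    i1 = exp.group1.index(reinforcement)
    i2 = exp.group2.index(reinforcement)
    return {"group_indices": (i1, i2), "pi": _reciprocal_mean(i1, i2)}


def _window_mean_index(series: pd.DataFrame, cs_plus_col: str, cs_minus_col: str,
                       window_s: float, period_s: float) -> float:
    lo = period_s - window_s
    sel = series[(series["t_s"] >= lo) & (series["t_s"] <= period_s)]
    if sel.empty or sel["t_s"].max() < period_s - 1.5:
        raise ValueError(
            f"series does not cover the final {window_s:g} s of the "
            f"{period_s:g} s choice period (last sample at "
            f"{series['t_s'].max():g} s)"
        )
    n_plus = sel[cs_plus_col].to_numpy(dtype=float)
    n_minus = sel[cs_minus_col].to_numpy(dtype=float)
    tot = n_plus + n_minus
    if np.any(tot <= 0):
        raise ValueError("zero flies counted in a window frame")
    return float(np.mean((n_minus - n_plus) / tot))


def tmaze_test_series(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    *,
    window_s: float = 10.0,
    period_s: float = 120.0,
    reinforcement: Reinforcement = "punishment",
) -> dict:
    """PI from per-frame arm counts over a choice period.

    Each group DataFrame needs columns ``t_s``, ``n_cs_plus``, ``n_cs_minus``.
    The per-group index is the time-averaged index over the final
    ``window_s`` seconds of the ``period_s`` choice period; the PI is the
    reciprocal mean.
    """
    idx = []
    for g in (group1, group2):
        v = _window_mean_index(g, "n_cs_plus", "n_cs_minus", window_s, period_s)
        idx.append(v if reinforcement == "punishment" else -v)
    return {"group_indices": tuple(idx), "pi": _reciprocal_mean(*idx)}


def visual_pi(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    *,
    cs_plus: tuple[str, str] = ("blue", "green"),
    reinforcement: Reinforcement = "punishment",
    convention: Literal["mean", "difference"] = "mean",
) -> dict:
    """Performance index of the quadrant color-learning test.

    Each group DataFrame holds per-frame quadrant counts (columns ``t_s``,
    ``n_blue``, ``n_green``; nominally 1 frame/s over a 90 s test).
    ``cs_plus`` gives the reinforced color per group. The per-group index is
    the time-averaged signed color preference; ``convention="mean"`` returns
    the mean of the two reciprocal indices, ``"difference"`` their sum (the
    between-group difference of raw preferences).
    """
    idx = []
    for g, plus in zip((group1, group2), cs_plus):
        if plus not in ("blue", "green"):
            raise ValueError("cs_plus entries must be 'blue' or 'green'")
        n_blue = g["n_blue"].to_numpy(dtype=float)
        n_green = g["n_green"].to_numpy(dtype=float)
        tot = n_blue + n_green
        if len(g) == 0:
            raise ValueError("empty count series")
        if np.any(tot <= 0):
            raise ValueError("zero flies counted in a test frame")
        pref_blue = float(np.mean((n_blue - n_green) / tot))
        avoid_cs_plus = -pref_blue if plus == "blue" else pref_blue
        idx.append(avoid_cs_plus if reinforcement == "punishment" else -avoid_cs_plus)
    if cs_plus[0] == cs_plus[1]:
        raise ValueError("reciprocal design needs swapped reinforced colors")
    pi = _reciprocal_mean(*idx) if convention == "mean" else float(sum(idx))
    return {"group_indices": tuple(idx), "pi": pi}


def ymaze_pi(trials: Sequence[tuple[int, int]]) -> dict:
    """Conditioned preference index of a reciprocal Y-maze odor-vs-air pair.

    ``trials`` is the reciprocal pair of ``(n_odor, n_air)`` counts; each
    trial's index is (odor - air) / total and the conditioned PI is the
    average over the pair.
    """
    if len(trials) != 2:
        raise ValueError("expected a reciprocal pair of trials")
    idx = []
    for n_odor, n_air in trials:
        if n_odor < 0 or n_air < 0:
            raise ValueError("counts must be non-negative")
        tot = n_odor + n_air
        if tot == 0:
            raise ValueError("trial has zero total flies")
        idx.append((n_odor - n_air) / tot)
    return {"trial_indices": tuple(idx), "pi": _reciprocal_mean(*idx)}
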
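"""Sleep scoring from Drosophila Activity Monitor (DAM) beam-crossing counts.

Single-beam DAM systems report the number of infrared-beam crossings per fly
per 1-min bin. Sleep is scored by the standard criterion: a sleep bout is a
maximal run of 5 or more consecutive minutes with zero counts; shorter
inactive runs contribute no sleep. The experimental design analyzed here
records 7 days at 12:12 LD: baseline days (1-3), thermogenetic-activation
days (4-5) and recovery (day 6 on). The activation effect is quantified as
the percent change of daily sleep on the activation days relative to the
last baseline day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "SleepBout",
    "detect_sleep_bouts",
    "sleep_mask",
    "daily_sleep",
    "sleep_profile",
    "percent_sleep_change",
    "cohort_percent_sleep_change",
    "waking_activity",
]

MINUTES_PER_DAY = 1440
MIN_BOUT_MIN = 5
DEFAULT_PHASES = {1: "baseline", 2: "baseline", 3: "baseline",
                  4: "activation", 5: "activation", 6: "recovery",
                  7: "recovery"}


@dataclass
class ActivityRecord:
    """Per-fly 1-min activity counts across whole experiment days.

    ``counts`` must cover complete days (multiples of 1440 minutes) with no
    missing bins; minute 0 of each day is lights-on and the light phase
    lasts ``light_minutes`` (12 h under 12:12 LD). ``phases`` labels each
    1-based day (e.g. baseline/activation/recovery).
    """

    channel: str
    counts: np.ndarray
    phases: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_PHASES))
    light_minutes: int = 720

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(np.isnan(self.counts.astype(float))):
            raise ValueError(
                f"channel {self.channel}: missing activity bins (no imputation)"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"channel {self.channel}: negative counts")
        if len(self.counts) == 0 or len(self.counts) % MINUTES_PER_DAY != 0:
            raise ValueError(
                f"channel {self.channel}: counts length {len(self.counts)} is "
                f"not a whole number of {MINUTES_PER_DAY}-min days"
            )
        self.counts = self.counts.astype(np.int64)
        missing = [d for d in range(1, self.n_days + 1) if d not in self.phases]
        if missing:
            raise ValueError(
                f"channel {self.channel}: days {missing} lack a phase label"
            )
        if not (0 < self.light_minutes < MINUTES_PER_DAY):
            raise ValueError("light_minutes must be within one day")

    @property
    def n_days(self) -> int:
        return len(self.counts) // MINUTES_PER_DAY

    def days_in_phase(self, phase: str) -> list[int]:
        return [d for d in range(1, self.n_days + 1) if self.phases[d] == phase]

    def is_dead(self, trailing_zero_min: int = 720) -> bool:
        """Dead-fly guard: a terminal run of zeros >= ``trailing_zero_min``
        (default 12 h) flags the channel for exclusion."""
        nz = np.nonzero(self.counts)[0]
        last_active = -1 if nz.size == 0 else int(nz[-1])
        return len(self.counts) - 1 - last_active >= trailing_zero_min


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of >= 5 consecutive zero-count minutes."""

    start: int  # global minute index from the start of the record
    duration: int  # minutes
    day: int  # 1-based day containing the bout start
    light_phase: str  # "light" | "dark" at bout start

    def __post_init__(self) -> None:
        if self.duration < MIN_BOUT_MIN:
            raise ValueError("sleep bouts are at least 5 min long")


def detect_sleep_bouts(record: ActivityRecord) -> list[SleepBout]:
    """Maximal runs of consecutive zero-count minutes of length >= 5."""
    inactive = record.counts == 0
    padded = np.concatenate([[False], inactive, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    bouts = []
    for s, e in zip(starts, ends):
        dur = int(e - s)
        if dur < MIN_BOUT_MIN:
            continue
        minute_of_day = s % MINUTES_PER_DAY
        bouts.append(
            SleepBout(
                start=int(s),
                duration=dur,
                day=int(s // MINUTES_PER_DAY) + 1,
                light_phase="light" if minute_of_day < record.light_minutes
                else "dark",
            )
        )
    return bouts


def sleep_mask(record: ActivityRecord) -> np.ndarray:
    """Boolean per-minute vector: True where the minute is inside a sleep bout."""
    mask = np.zeros(len(record.counts), dtype=bool)
    for b in detect_sleep_bouts(record):
        mask[b.start:b.start + b.duration] = True
    return mask


def daily_sleep(record: ActivityRecord) -> pd.DataFrame:
    """Minutes of sleep per day, with the light/dark (day/night) split.

    Bouts spanning a day or light-phase boundary are apportioned by minutes.
    Returns a DataFrame indexed by day with columns ``sleep_min``,
    ``day_sleep_min``, ``night_sleep_min`` and ``phase``.
    """
    mask = sleep_mask(record).reshape(record.n_days, MINUTES_PER_DAY)
    light = np.arange(MINUTES_PER_DAY) < record.light_minutes
    total = mask.sum(axis=1)
    day_part = mask[:, light].sum(axis=1)
    days = np.arange(1, record.n_days + 1)
    return pd.DataFrame(
        {
            "sleep_min": total,
            "day_sleep_min": day_part,
            "night_sleep_min": total - day_part,
            "phase": [record.phases[d] for d in days],
        },
        index=pd.Index(days, name="day"),
    )


def sleep_profile(records: Sequence[ActivityRecord], bin_min: int = 30) -> pd.DataFrame:
    """Mean sleep minutes per ``bin_min`` bin across flies, per day.

    Returns a DataFrame indexed by (day, bin_start_min) with column
    ``sleep_min`` (48 bins/day at the default 30-min bin).
    """
    records = list(records)
    if not records:
        raise ValueError("sleep_profile requires at least one record")
    if MINUTES_PER_DAY % bin_min != 0:
        raise ValueError("bin_min must divide 1440")
    n_days = records[0].n_days
    if any(r.n_days != n_days for r in records):
        raise ValueError("all records must cover the same number of days")
    nbins = MINUTES_PER_DAY // bin_min
    acc = np.zeros((n_days, nbins))
    for r in records:
        m = sleep_mask(r).reshape(n_days, nbins, bin_min)
        acc += m.sum(axis=2)
    acc /= len(records)
    idx = pd.MultiIndex.from_product(
        [range(1, n_days + 1), range(0, MINUTES_PER_DAY, bin_min)],
        names=["day", "bin_start_min"],
    )
    return pd.DataFrame({"sleep_min": acc.ravel()}, index=idx)


def percent_sleep_change(
    record: ActivityRecord,
    baseline_day: int = 3,
    activation_days: Sequence[int] = (4, 5),
) -> float:
    """Percent change of daily sleep on the activation days relative to the
    baseline day: 100 * (mean(activation) - baseline) / baseline.

    Negative values mean decreased sleep. Returns NaN (flagged undefined)
    when the baseline day has zero sleep.
    """
    ds = daily_sleep(record)["sleep_min"]
    for d in (baseline_day, *activation_days):
        if d not in ds.index:
            raise ValueError(f"day {d} not present in record {record.channel}")
    base = float(ds.loc[baseline_day])
    if base == 0:
        return float("nan")
    act = float(np.mean([ds.loc[d] for d in activation_days]))
    return 100.0 * (act - base) / base


def cohort_percent_sleep_change(
    records: Sequence[ActivityRecord],
    baseline_day: int = 3,
    activation_days: Sequence[int] = (4, 5),
    exclude_dead: bool = True,
) -> dict:
    """Per-fly percent sleep changes plus both cohort aggregations.

    ``mean_of_flies`` averages the per-fly percent changes (flies with a
    zero-sleep baseline are flagged and skipped); ``of_cohort_means``
    computes the percent change of cohort-mean daily sleep.
    """
    records = list(records)
    used, excluded = [], []
    for r in records:
        (excluded if exclude_dead and r.is_dead() else used).append(r)
    per_fly = {
        r.channel: percent_sleep_change(r, baseline_day, activation_days)
        for r in used
    }
    vals = np.array([v for v in per_fly.values() if not np.isnan(v)])
    base_means = [float(daily_sleep(r)["sleep_min"].loc[baseline_day]) for r in used]
    act_means = [
        float(np.mean([daily_sleep(r)["sleep_min"].loc[d] for d in activation_days]))
        for r in used
    ]
    base = float(np.mean(base_means)) if base_means else float("nan")
    act = float(np.mean(act_means)) if act_means else float("nan")
    return {
        "per_fly": per_fly,
        "n_undefined": int(sum(np.isnan(v) for v in per_fly.values())),
        "n_excluded_dead": len(excluded),
        "excluded_channels": [r.channel for r in excluded],
        "mean_of_flies": float(vals.mean()) if vals.size else float("nan"),
        "of_cohort_means": 100.0 * (act - base) / base if base else float("nan"),
    }


def waking_activity(record: ActivityRecord) -> float:
    """Beam crossings per awake minute: total counts divided by the number
    of minutes not inside any sleep bout. NaN when the fly is never awake."""
    mask = sleep_mask(record)
    awake = int((~mask).sum())
    if awake == 0:
        return float("nan")
    return float(record.counts.sum()) / awake
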
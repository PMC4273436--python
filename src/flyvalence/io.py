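"""Readers and writers for trajectories, DAM activity, count tables and configs.

All readers are strict: malformed rows, duplicated (fly, frame) samples,
non-contiguous DAM minutes or unit-inconsistent positions raise instead of
being silently repaired. Behavioral pipelines accumulate too many silent
data errors otherwise.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .arena import ArenaConfig, Epoch, IlluminationSchedule, Trajectory
from .memory import GroupCounts, ReciprocalExperiment
from .sleep import ActivityRecord, DEFAULT_PHASES, MINUTES_PER_DAY

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "read_dam",
    "write_dam_csv",
    "read_reciprocal_counts",
    "read_config",
    "write_config",
]

TRAJECTORY_COLUMNS = ["frame", "fly_id", "t_s", "x_mm", "y_mm"]
DAM_CSV_COLUMNS = ["channel", "day", "minute", "count"]


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write a cohort as tidy CSV (`frame,fly_id,t_s,x_mm,y_mm`)."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {"frame": tr.frame, "fly_id": tr.fly_id, "t_s": tr.t,
                 "x_mm": tr.x, "y_mm": tr.y}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path, config: ArenaConfig) -> tuple[list[Trajectory], dict]:
    """Read and validate a trajectory CSV.

    Returns ``(trajectories, gap_report)`` where the report maps fly_id to
    its number of missing frames. Raises on a malformed header, duplicated
    (fly, frame) rows, times inconsistent with the frame rate, out-of-arena
    positions, or positions whose scale suggests a unit mistake (cm vs mm).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(TRAJECTORY_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df[["frame", "t_s", "x_mm", "y_mm"]].isna().any().any():
        bad = int(df[df[["frame", "t_s", "x_mm", "y_mm"]].isna().any(axis=1)].index[0])
        raise ValueError(f"{path}: malformed row at line {bad + 2}")
    dup = df.duplicated(subset=["fly_id", "frame"])
    if dup.any():
        line = int(df.index[dup][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: duplicated (fly_id, frame) at line {line}")

    r = np.hypot(df["x_mm"], df["y_mm"])
    # unit sanity: all positions clustered deep inside the arena suggests
    # centimeters were written where millimeters were expected
    if float(r.max()) < 0.25 * config.radius:
        raise ValueError(
            f"{path}: maximum radial position {r.max():.2f} mm is implausibly "
            f"small for a {config.radius} mm arena; positions look like the "
            "wrong unit (cm vs mm). Refusing to rescale silently."
        )

    t_expect = df["frame"] / config.frame_rate
    if float((df["t_s"] - t_expect).abs().max()) > 0.5 / config.frame_rate:
        raise ValueError(
            f"{path}: t_s column inconsistent with frame/frame_rate "
            f"({config.frame_rate} Hz)"
        )

    trajectories, gaps = [], {}
    for fly_id, g in df.groupby("fly_id", sort=True):
        g = g.sort_values("frame")
        tr = Trajectory(
            fly_id=str(fly_id),
            frame=g["frame"].to_numpy(dtype=np.int64),
            t=g["t_s"].to_numpy(dtype=float),
            x=g["x_mm"].to_numpy(dtype=float),
            y=g["y_mm"].to_numpy(dtype=float),
        )
        tr.validate_bounds(config)
        span = int(tr.frame[-1] - tr.frame[0]) + 1
        gaps[tr.fly_id] = span - len(tr)
        trajectories.append(tr)
    return trajectories, gaps


def write_dam_csv(records: Sequence[ActivityRecord], path) -> None:
    """Write activity records as simplified CSV (`channel,day,minute,count`)."""
    rows = []
    for r in records:
        days = np.repeat(np.arange(1, r.n_days + 1), MINUTES_PER_DAY)
        minutes = np.tile(np.arange(MINUTES_PER_DAY), r.n_days)
        rows.append(
            pd.DataFrame(
                {"channel": r.channel, "day": days, "minute": minutes,
                 "count": r.counts}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _read_dam_csv(path, phases, light_minutes) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    if list(df.columns) != DAM_CSV_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(DAM_CSV_COLUMNS)}"
        )
    records = []
    for ch, g in df.groupby("channel", sort=True):
        g = g.sort_values(["day", "minute"])
        minute_index = (g["day"].to_numpy() - 1) * MINUTES_PER_DAY + g[
            "minute"
        ].to_numpy()
        expected = np.arange(minute_index[0], minute_index[0] + len(g))
        if minute_index[0] != 0 or not np.array_equal(minute_index, expected):
            missing = int(np.setdiff1d(expected, minute_index)[:1][0]) if len(
                np.setdiff1d(expected, minute_index)
            ) else int(minute_index[0])
            raise ValueError(
                f"{path}: channel {ch} has non-contiguous minutes "
                f"(first problem at absolute minute {missing})"
            )
        records.append(
            ActivityRecord(
                channel=str(ch),
                counts=g["count"].to_numpy(),
                phases=dict(phases),
                light_minutes=light_minutes,
            )
        )
    return records


def _read_dam_monitor(path, phases, light_minutes, lights_on: str):
    """Trikinetics monitor file: tab-delimited rows of reading index, date,
    time, status code, then (ending with) 32 channel counts. Rows whose
    status code is not 1 are rejected and reported."""
    timestamps = []
    data = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4 + 32:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 36 tab-separated fields, "
                    f"got {len(fields)}"
                )
            status = fields[3].strip()
            if status != "1":
                rejected += 1
                continue
            try:
                ts = pd.to_datetime(
                    fields[1].strip() + " " + fields[2].strip(),
                    format="%d %b %y %H:%M:%S",
                )
                counts = [int(v) for v in fields[-32:]]
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})")
            timestamps.append(ts)
            data.append(counts)
    if not data:
        raise ValueError(f"{path}: no valid data rows")
    ts = pd.DatetimeIndex(timestamps)
    if not ts.is_monotonic_increasing:
        raise ValueError(f"{path}: timestamps are not monotonically increasing")
    step = np.diff(ts.asi8) // 60_000_000_000
    if np.any(step != 1):
        i = int(np.argmax(step != 1))
        raise ValueError(
            f"{path}: missing minutes between {ts[i]} and {ts[i + 1]}"
        )
    on_h, on_m = (int(v) for v in lights_on.split(":"))
    first = ts[0]
    offset = (first.hour * 60 + first.minute) - (on_h * 60 + on_m)
    if offset % MINUTES_PER_DAY != 0:
        raise ValueError(
            f"{path}: recording must start at lights-on ({lights_on}); "
            f"first reading at {first.time()}"
        )
    arr = np.asarray(data, dtype=np.int64)
    records = [
        ActivityRecord(
            channel=f"ch{j + 1:02d}",
            counts=arr[:, j],
            phases=dict(phases),
            light_minutes=light_minutes,
        )
        for j in range(arr.shape[1])
    ]
    return records, {"rows_rejected": rejected}


def read_dam(
    path,
    phases: Optional[dict] = None,
    light_minutes: int = 720,
    lights_on: str = "08:00",
) -> tuple[list[ActivityRecord], dict]:
    """Read DAM activity from a Trikinetics monitor file or simplified CSV.

    Returns ``(records, report)``; the report counts rejected monitor rows.
    """
    phases = phases or dict(DEFAULT_PHASES)
    with open(path) as fh:
        head = fh.readline()
    if "\t" in head:
        return _read_dam_monitor(path, phases, light_minutes, lights_on)
    return _read_dam_csv(path, phases, light_minutes), {"rows_rejected": 0}


def read_reciprocal_counts(path, modality: str = "olfactory_tmaze") -> ReciprocalExperiment:
    """Read a trial count table CSV (`group,cs_plus,arm,count`) into a
    reciprocal experiment."""
    df = pd.read_csv(path)
    expected = ["group", "cs_plus", "arm", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    groups = {}
    for gname, g in df.groupby("group", sort=True):
        cs = g["cs_plus"].unique()
        if len(cs) != 1:
            raise ValueError(f"{path}: group {gname} has conflicting cs_plus")
        counts = dict(zip(g["arm"], g["count"].astype(int)))
        groups[gname] = GroupCounts(cs_plus=str(cs[0]), counts=counts)
    if len(groups) != 2:
        raise ValueError(f"{path}: expected exactly 2 groups, got {len(groups)}")
    g1, g2 = (groups[k] for k in sorted(groups))
    return ReciprocalExperiment(group1=g1, group2=g2, modality=modality)


def schedule_to_dict(schedule: IlluminationSchedule) -> list:
    return [
        {"t_start": e.t_start, "t_end": e.t_end, "lit": sorted(e.lit)}
        for e in schedule.epochs
    ]


def schedule_from_dict(epochs: list) -> IlluminationSchedule:
    return IlluminationSchedule(
        tuple(Epoch(e["t_start"], e["t_end"], frozenset(e["lit"])) for e in epochs)
    )


def write_config(config: ArenaConfig, schedule: IlluminationSchedule, path) -> None:
    doc = {
        "arena": {
            "radius": config.radius,
            "choice_halfwidth": config.choice_halfwidth,
            "center_exclusion_radius": config.center_exclusion_radius,
            "frame_rate": config.frame_rate,
            "intensity_max": config.intensity_max,
            "intensity_min_at_border": config.intensity_min_at_border,
            "gradient_length": config.gradient_length,
            "bounds_tolerance": config.bounds_tolerance,
        },
        "schedule": schedule_to_dict(schedule),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_config(path) -> tuple[ArenaConfig, IlluminationSchedule]:
    """Read arena + schedule from a YAML config; missing sections fall back
    to the standard protocol defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    config = ArenaConfig(**doc.get("arena", {}))
    sched = doc.get("schedule")
    schedule = schedule_from_dict(sched) if sched else IlluminationSchedule.default()
    return config, schedule
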
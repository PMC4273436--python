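"""End-to-end analysis bundles and the disk-writing pipeline runner.

`analyze_arena_video` is the library-level composition used everywhere: one
video's trajectories in, preference series, PI, choice-zone events and the
per-video summary out. `run_pipeline` drives simulate/analyze stages from a
single run configuration, writes CSV tables plus JSON summaries to an output
directory and records a provenance file (config echo, seed, package version,
input checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .arena import ArenaConfig, IlluminationSchedule, Trajectory
from .choice_zone import (
    ChoiceEvent,
    choice_probability,
    exit_fractions,
    filter_events,
    segment_choice_events,
    state_conditioned_kinematics,
)
from .io import (
    read_config,
    read_trajectories,
    schedule_to_dict,
    write_trajectories,
)
from .preference import light_preference_index, preference_timeseries
from .synth import AgentParams, simulate_arena_cohort

__all__ = ["analyze_arena_video", "events_to_frame", "run_pipeline"]


def events_to_frame(events: Sequence[ChoiceEvent]) -> pd.DataFrame:
    """Tabulate choice events for CSV output."""
    return pd.DataFrame(
        [
            {
                "fly_id": ev.fly_id,
                "t_entry": ev.t_entry,
                "entry_side": ev.entry_side,
                "entry_angle_deg": ev.entry_angle,
                "prior_disp_mm": ev.prior_displacement,
                "outcome": ev.outcome,
                "exit_side": ev.exit_side,
                "t_exit": ev.t_exit,
            }
            for ev in events
        ]
    )


def analyze_arena_video(
    trajectories: Sequence[Trajectory],
    config: ArenaConfig,
    schedule: IlluminationSchedule,
    *,
    angle_min: float = 45.0,
    angle_max: float = 135.0,
    min_prior_mm: float = 5.0,
) -> dict:
    """Full analysis of one video: preference series + PI, filtered choice
    events, exit fractions, choice probability and state-conditioned
    kinematics.

    Returns a dict with keys ``series`` (DataFrame), ``pi`` (window PIs and
    overall PI), ``events``/``kept_events`` (lists), ``event_counts``,
    ``fractions``, ``choice_probability`` (NaN when no retained event) and
    ``kinematics``.
    """
    series = preference_timeseries(trajectories, schedule, config)
    pi = light_preference_index(series, schedule)

    all_events: list[ChoiceEvent] = []
    seg_info = {"n_events": 0, "n_censored": 0, "censor_reasons": {}}
    for tr in trajectories:
        evs, info = segment_choice_events(tr, config, schedule)
        all_events.extend(evs)
        seg_info["n_events"] += info["n_events"]
        seg_info["n_censored"] += info["n_censored"]
        for k, v in info["censor_reasons"].items():
            seg_info["censor_reasons"][k] = (
                seg_info["censor_reasons"].get(k, 0) + v
            )
    kept, filter_counts = filter_events(
        all_events, angle_min=angle_min, angle_max=angle_max,
        min_prior_mm=min_prior_mm,
    )
    fractions = exit_fractions(kept)
    cp = choice_probability(kept) if kept else float("nan")
    kin = state_conditioned_kinematics(trajectories, schedule, config)
    return {
        "series": series,
        "pi": pi,
        "events": all_events,
        "kept_events": kept,
        "event_counts": {**seg_info, **filter_counts},
        "fractions": fractions,
        "choice_probability": cp,
        "kinematics": kin,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(run_config: dict, out_dir) -> dict:
    """Execute the stages named in ``run_config`` and write results.

    Supported keys:

    * ``seed`` (int, required) — the single seed all randomness flows from.
    * ``arena_config`` (path to YAML, optional) — arena + schedule.
    * ``simulate_arena`` (dict of AgentParams overrides, optional) — run the
      cohort simulator and write ``trajectories.csv``.
    * ``trajectories`` (path, optional) — analyze an existing trajectory CSV
      instead of simulating.
    * ``analysis`` (dict, optional) — filter overrides
      (``angle_min``/``angle_max``/``min_prior_mm``).

    Writes ``preference.csv``, ``events.csv``, ``summary.json`` and
    ``provenance.json``; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "seed" not in run_config:
        raise ValueError("run config must set a seed")
    seed = int(run_config["seed"])

    checksums = {}
    if run_config.get("arena_config"):
        cfg_path = Path(run_config["arena_config"])
        if not cfg_path.exists():
            raise FileNotFoundError(f"config file not found: {cfg_path}")
        config, schedule = read_config(cfg_path)
        checksums[str(cfg_path)] = _sha256(cfg_path)
    else:
        config, schedule = ArenaConfig(), IlluminationSchedule.default()

    if run_config.get("trajectories"):
        traj_path = Path(run_config["trajectories"])
        if not traj_path.exists():
            raise FileNotFoundError(f"trajectory file not found: {traj_path}")
        trajectories, gaps = read_trajectories(traj_path, config)
        checksums[str(traj_path)] = _sha256(traj_path)
    elif "simulate_arena" in run_config:
        params = AgentParams(seed=seed, **run_config["simulate_arena"])
        trajectories = simulate_arena_cohort(params, config, schedule)
        write_trajectories(trajectories, out / "trajectories.csv")
        gaps = {tr.fly_id: 0 for tr in trajectories}
    else:
        raise ValueError(
            "run config must provide either 'trajectories' or 'simulate_arena'"
        )

    analysis = run_config.get("analysis", {})
    result = analyze_arena_video(trajectories, config, schedule, **analysis)

    result["series"].to_csv(out / "preference.csv", float_format="%.6f")
    events_to_frame(result["events"]).to_csv(
        out / "events.csv", index=False, float_format="%.6f"
    )
    summary = _jsonable(
        {
            "pi": result["pi"],
            "event_counts": result["event_counts"],
            "fractions": result["fractions"],
            "choice_probability": result["choice_probability"],
            "kinematics": result["kinematics"],
            "gap_report": gaps,
        }
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    provenance = {
        "package": "flyvalence",
        "version": __version__,
        "seed": seed,
        "config_echo": _jsonable(
            {"arena": asdict(config), "schedule": schedule_to_dict(schedule),
             "run": {k: v for k, v in run_config.items()}}
        ),
        "input_checksums": checksums,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    return summary
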
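"""Per-frame quadrant preference and the red-light preference index (PI).

For a cohort of flies tracked in the quadrant arena, the quadrant preference
at each frame is

    q_pref = (N_Q2 + N_Q3 - N_Q1 - N_Q4) / N

and, during light-on epochs, the light preference is

    light_pref = (N_lit - N_unlit) / N

where N counts the flies tracked in that frame. The overall preference index
of a 2-min experiment is the mean of the time-averaged light preference over
the final 5 s of each light-on epoch (55-60 s and 115-120 s under the
default protocol). One video of ~20 flies yields one PI; the video is the
replicate unit for group statistics.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig, IlluminationSchedule, Trajectory, quadrant_codes

__all__ = ["preference_timeseries", "light_preference_index"]

_Q23 = (2, 3)
_Q14 = (1, 4)


def preference_timeseries(
    trajectories: Sequence[Trajectory],
    schedule: IlluminationSchedule,
    config: ArenaConfig,
) -> pd.DataFrame:
    """Per-frame preference series for a cohort.

    Returns a DataFrame indexed by frame with columns ``t_s``, ``q_pref``,
    ``light_pref`` and ``n_flies``. Frames where no fly is tracked are
    dropped (the preference is undefined, not zero); ``light_pref`` is NaN
    outside light-on epochs.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("preference_timeseries requires at least one trajectory")
    for tr in trajectories:
        tr.validate_bounds(config)

    frames = np.concatenate([tr.frame for tr in trajectories])
    ts = np.concatenate([tr.t for tr in trajectories])
    codes = np.concatenate(
        [quadrant_codes(tr.x, tr.y) for tr in trajectories]
    ).astype(np.int64)

    # restrict to the schedule span
    keep = (ts >= schedule.t_start) & (ts <= schedule.t_end)
    frames, ts, codes = frames[keep], ts[keep], codes[keep]
    if frames.size == 0:
        raise ValueError("no tracked samples fall within the schedule span")

    uniq, inv = np.unique(frames, return_inverse=True)
    nf = uniq.size
    counts = np.zeros((nf, 5), dtype=np.int64)  # columns 1..4 used
    np.add.at(counts, (inv, codes), 1)

    # one representative time per frame
    t_per_frame = np.zeros(nf)
    t_per_frame[inv] = ts

    n = counts[:, 1:].sum(axis=1)
    q_pref = (counts[:, 2] + counts[:, 3] - counts[:, 1] - counts[:, 4]) / n

    light_pref = np.full(nf, np.nan)
    for epoch in schedule.light_on_epochs():
        lit_codes = sorted(int(q[1]) for q in epoch.lit)
        in_epoch = (t_per_frame >= epoch.t_start) & (t_per_frame < epoch.t_end)
        n_lit = counts[:, lit_codes].sum(axis=1)
        light_pref[in_epoch] = ((2 * n_lit - n) / n)[in_epoch]

    return pd.DataFrame(
        {"t_s": t_per_frame, "q_pref": q_pref, "light_pref": light_pref,
         "n_flies": n},
        index=pd.Index(uniq, name="frame"),
    )


def light_preference_index(
    series: pd.DataFrame,
    schedule: IlluminationSchedule,
    window_s: float = 5.0,
) -> dict:
    """Overall PI: mean over light-on epochs of the time-averaged light
    preference in the final ``window_s`` seconds of each epoch.

    Returns ``{"window_pis": [...], "pi": float}``. Raises if the schedule
    has no light-on epoch or if a window is not covered by the series.
    """
    epochs = schedule.light_on_epochs()
    if not epochs:
        raise ValueError("schedule contains no light-on epoch")
    window_pis = []
    missing = []
    for epoch in epochs:
        lo, hi = epoch.t_end - window_s, epoch.t_end
        sel = series[(series["t_s"] >= lo) & (series["t_s"] < hi)]
        vals = sel["light_pref"].to_numpy()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            missing.append((lo, hi))
            continue
        window_pis.append(float(np.mean(vals)))
    if missing:
        spans = ", ".join(f"{lo:g}-{hi:g} s" for lo, hi in missing)
        raise ValueError(f"series does not cover PI window(s): {spans}")
    return {"window_pis": window_pis, "pi": float(np.mean(window_pis))}
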
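"""Choice-zone segmentation, entry filters, exit classification and kinematics."""

import numpy as np
import pytest

from flyvalence import (
    AgentParams,
    ChoiceEvent,
    Trajectory,
    choice_probability,
    exit_fractions,
    filter_events,
    kinematics,
    segment_choice_events,
    simulate_arena_cohort,
    state_conditioned_kinematics,
)
from flyvalence.arena import illumination_state, in_choice_zone, quadrant_codes


def _straight_track(config, *, y=30.0, x_from=-20.0, x_to=10.0, t_start=95.0,
                    step=0.5):
    """Constant-velocity track along +x at fixed y, starting at t_start."""
    n = int(round((x_to - x_from) / step)) + 1
    x = x_from + step * np.arange(n)
    frame0 = int(round(t_start * config.frame_rate))
    return Trajectory.from_positions("f0", x, np.full(n, y), config,
                                     frame_start=frame0)


def test_straight_crossing_yields_one_crossing_event(config, schedule):
    # during 90-120 s, Q1&4 are lit: travelling -x -> +x at y=30 crosses
    # from unlit Q2 into lit Q1
    tr = _straight_track(config)
    events, info = segment_choice_events(tr, config, schedule)
    assert len(events) == 1
    ev = events[0]
    assert ev.outcome == "crossing"
    assert ev.entry_side == "unlit" and ev.exit_side == "lit"
    assert ev.entry_border == "vertical"
    assert ev.entry_angle == pytest.approx(90.0)
    assert ev.prior_displacement == pytest.approx(15.0)  # 0.5 mm/frame at 30 fps


def test_constructed_turnaround(config, schedule):
    y = 30.0
    out_leg = np.arange(-20, -1.0, 0.5)
    back = out_leg[::-1]
    x = np.concatenate([out_leg, [-1.0], back])
    frame0 = int(round(95.0 * config.frame_rate))
    tr = Trajectory.from_positions("f0", x, np.full(len(x), y), config,
                                   frame_start=frame0)
    events, _ = segment_choice_events(tr, config, schedule)
    assert len(events) == 1
    assert events[0].outcome == "turnaround"
    assert events[0].entry_side == events[0].exit_side == "unlit"


def test_event_straddling_epoch_boundary_censored(config, schedule):
    # entry at ~59.5 s in the lit epoch, exit after the 60 s transition
    tr = _straight_track(config, t_start=58.5, x_to=8.0)
    events, info = segment_choice_events(tr, config, schedule)
    assert len(events) == 1
    assert events[0].outcome == "censored"
    assert events[0].censor_reason == "epoch_boundary"
    assert info["n_censored"] == 1


def test_entry_in_settle_window_censored(config, schedule):
    # entry 0.5 s after the lights switch at 90 s
    tr = _straight_track(config, t_start=89.5)
    events, _ = segment_choice_events(tr, config, schedule)
    assert len(events) == 1
    assert events[0].censor_reason == "epoch_settle"


def test_event_in_dark_epoch_censored(config, schedule):
    tr = _straight_track(config, t_start=65.0)
    events, _ = segment_choice_events(tr, config, schedule)
    assert events and all(e.censor_reason == "dark_epoch" for e in events)


def test_track_loss_censors_event(config, schedule):
    tr = _straight_track(config, x_to=-2.0)  # ends inside the band
    events, info = segment_choice_events(tr, config, schedule)
    assert len(events) == 1
    assert events[0].censor_reason == "track_loss"


def test_gap_inside_event_censors(config, schedule):
    tr = _straight_track(config)
    # remove one in-band sample to create a tracking gap
    idx = np.flatnonzero(np.abs(tr.x) < 3.0)[0]
    keep = np.ones(len(tr), dtype=bool)
    keep[idx] = False
    tr2 = Trajectory("f0", tr.frame[keep], tr.t[keep], tr.x[keep], tr.y[keep])
    events, _ = segment_choice_events(tr2, config, schedule)
    assert any(e.censor_reason == "tracking_gap" for e in events)


def test_entry_angle_45_degrees(config, schedule):
    # heading with dx = dy approaches the vertical border at 45 degrees
    n = 80
    step = 0.4
    x = -20.0 + step * np.arange(n)
    y = 5.0 + step * np.arange(n)
    frame0 = int(round(95.0 * config.frame_rate))
    tr = Trajectory.from_positions("f0", x, y, config, frame_start=frame0)
    events, _ = segment_choice_events(tr, config, schedule)
    assert events
    assert events[0].entry_angle == pytest.approx(45.0, abs=1.0) or \
        events[0].entry_angle == pytest.approx(135.0, abs=1.0)


def _event(angle, prior, outcome="crossing", entry="unlit"):
    exit_side = ("lit" if entry == "unlit" else "unlit") if outcome == "crossing" else entry
    return ChoiceEvent(
        fly_id="f", t_entry=40.0, frame_entry=1200, entry_border="vertical",
        entry_side=entry, entry_angle=angle, prior_displacement=prior,
        t_exit=41.0, exit_side=exit_side, outcome=outcome,
    )


def test_filter_bounds():
    kept, counts = filter_events(
        [
            _event(90.0, 8.0),      # kept
            _event(30.0, 8.0),      # angle out of [45, 135]
            _event(45.0, 8.0),      # inclusive bound kept
            _event(135.0, 8.0),     # inclusive bound kept
            _event(90.0, 5.0),      # strict > 5 mm: dropped
            _event(90.0, 5.01),     # kept
        ]
    )
    assert counts["kept"] == 4
    assert counts["angle_rejected"] == 1
    assert counts["prior_rejected"] == 1


def test_filter_drops_censored_and_unfilterable():
    ev_censored = ChoiceEvent("f", 40.0, 1200, "vertical", "unlit")
    ev_noangle = _event(None, 8.0)
    kept, counts = filter_events([ev_censored, ev_noangle])
    assert kept == []
    assert counts["censored"] == 1 and counts["unfilterable"] == 1


def test_exit_fractions_wilson_oracle():
    events = [_event(90, 8, "crossing") for _ in range(5)] + [
        _event(90, 8, "turnaround") for _ in range(5)
    ]
    out = exit_fractions(events)
    res = out["unlit"]
    assert res["n"] == 10 and res["n_exit_lit"] == 5
    assert res["fraction_exit_lit"] == pytest.approx(0.5)
    # closed-form Wilson interval at z = 1.959964, p-hat = 0.5, n = 10
    z = 1.959963984540054
    center = (0.5 + z**2 / 20) / (1 + z**2 / 10)
    halfw = (z / (1 + z**2 / 10)) * np.sqrt(0.25 / 10 + z**2 / 400)
    assert res["ci95"][0] == pytest.approx(center - halfw, abs=1e-9)
    assert res["ci95"][1] == pytest.approx(center + halfw, abs=1e-9)
    assert out["lit"] is None  # no lit-side entries


def test_all_dark_entries_exit_lit():
    events = [_event(90, 8, "crossing") for _ in range(7)]
    assert exit_fractions(events)["unlit"]["fraction_exit_lit"] == 1.0


def test_choice_probability_hand_arithmetic():
    events = (
        [_event(90, 8, "crossing", "unlit") for _ in range(3)]     # dark->lit
        + [_event(90, 8, "turnaround", "unlit") for _ in range(7)]  # dark->dark
        + [_event(90, 8, "turnaround", "lit") for _ in range(2)]    # lit->lit
        + [_event(90, 8, "crossing", "lit") for _ in range(8)]      # lit->dark
    )
    assert choice_probability(events) == pytest.approx(5 / 20)
    # complement identity: 1 - fraction exiting dark
    frac_dark = sum(e.exit_side == "unlit" for e in events) / len(events)
    assert choice_probability(events) == pytest.approx(1 - frac_dark)


def test_choice_probability_empty_raises():
    with pytest.raises(ValueError):
        choice_probability([])


def test_kinematics_straight_motion(config):
    tr = _straight_track(config, t_start=10.0)
    kin = kinematics(tr, config)
    assert np.isnan(kin["speed"].iloc[0])
    assert kin["speed"].iloc[1:].to_numpy() == pytest.approx(15.0)
    assert kin["angular_speed"].iloc[2:].to_numpy() == pytest.approx(0.0)


def test_kinematics_stationary_fly(config):
    tr = Trajectory.from_positions("f0", np.full(30, 20.0), np.full(30, 20.0),
                                   config)
    kin = kinematics(tr, config)
    assert kin["speed"].iloc[1:].to_numpy() == pytest.approx(0.0)
    # heading undefined below the speed threshold
    assert np.isnan(kin["angular_speed"].iloc[2:]).all()


def test_kinematics_circle_matches_analytic_rate(config):
    # constant-rate circle: 3 deg/frame = 90 deg/s at 30 fps
    n = 200
    theta = np.radians(3.0) * np.arange(n)
    tr = Trajectory.from_positions("f0", 20 * np.cos(theta), 20 * np.sin(theta),
                                   config)
    kin = kinematics(tr, config)
    ang = kin["angular_speed"].iloc[2:].to_numpy()
    assert np.nanmean(ang) == pytest.approx(90.0, rel=0.02)
    speed = kin["speed"].iloc[1:].to_numpy()
    chord = 2 * 20 * np.sin(np.radians(1.5))
    assert np.nanmean(speed) == pytest.approx(chord * 30, rel=1e-6)


def test_kinematics_gap_yields_nan(config):
    tr0 = _straight_track(config, t_start=10.0)
    keep = np.ones(len(tr0), dtype=bool)
    keep[10] = False
    tr = Trajectory("f0", tr0.frame[keep], tr0.t[keep], tr0.x[keep], tr0.y[keep])
    kin = kinematics(tr, config)
    assert np.isnan(kin["speed"].iloc[10])  # frame after the gap


def _bruteforce_events(tr, config, schedule, settle_s=1.0):
    """Independent per-frame state-machine scan (the oracle)."""
    out = []
    inside = [in_choice_zone((xi, yi), config) for xi, yi in zip(tr.x, tr.y)]
    i = 0
    n = len(tr)
    while i < n and inside[i]:
        i += 1
    while i < n:
        if not inside[i]:
            i += 1
            continue
        pre = i - 1
        j = i
        gap = tr.frame[i] != tr.frame[pre] + 1
        while j < n and inside[j]:
            if j > i and tr.frame[j] != tr.frame[j - 1] + 1:
                gap = True
            j += 1
        lost = j >= n
        if not lost and tr.frame[j] != tr.frame[j - 1] + 1:
            gap = True
        epoch = schedule.epoch_at(float(tr.t[pre]))
        state = None
        if gap or lost or not epoch.lit:
            state = "censored"
        elif schedule.epoch_at(float(tr.t[j])) is not epoch:
            state = "censored"
        elif float(tr.t[i]) - epoch.t_start < settle_s:
            state = "censored"
        elif np.hypot(tr.x[pre], tr.y[pre]) < config.center_exclusion_radius:
            state = "censored"
        elif np.hypot(tr.x[j], tr.y[j]) < config.center_exclusion_radius:
            state = "censored"
        if state == "censored":
            out.append((int(tr.frame[i]), None, None, "censored"))
        else:
            entry = illumination_state((tr.x[pre], tr.y[pre]), float(tr.t[pre]),
                                       schedule, config)
            exit_ = illumination_state((tr.x[j], tr.y[j]), float(tr.t[j]),
                                       schedule, config)
            outcome = "crossing" if entry != exit_ else "turnaround"
            out.append((int(tr.frame[i]), entry, exit_, outcome))
        i = j
    return out


def test_segmentation_matches_bruteforce_scan(config, schedule):
    trajs = simulate_arena_cohort(AgentParams(n_flies=20, valence=-0.5, seed=42),
                                  config, schedule)
    for tr in trajs:
        events, _ = segment_choice_events(tr, config, schedule)
        got = [
            (ev.frame_entry,
             None if ev.outcome == "censored" else ev.entry_side,
             None if ev.outcome == "censored" else ev.exit_side,
             ev.outcome)
            for ev in events
        ]
        assert got == _bruteforce_events(tr, config, schedule)


def test_event_conservation(config, schedule):
    trajs = simulate_arena_cohort(AgentParams(n_flies=10, valence=0.4, seed=7),
                                  config, schedule)
    for tr in trajs:
        events, info = segment_choice_events(tr, config, schedule)
        n_cross = sum(e.outcome == "crossing" for e in events)
        n_turn = sum(e.outcome == "turnaround" for e in events)
        n_cens = sum(e.outcome == "censored" for e in events)
        assert n_cross + n_turn + n_cens == info["n_events"] == len(events)
        # events are disjoint in time
        for a, b in zip(events, events[1:]):
            assert b.frame_entry > a.frame_entry


def test_state_conditioned_speed_ratio_recovery(config, schedule):
    ratios = []
    for seed in range(3):
        trajs = simulate_arena_cohort(
            AgentParams(lit_speed_multiplier=1.5, seed=100 + seed),
            config, schedule)
        k = state_conditioned_kinematics(trajs, schedule, config)
        ratios.append(k["speed_lit"] / k["speed_unlit"])
    assert np.mean(ratios) == pytest.approx(1.5, rel=0.1)


def test_state_conditioned_null_kinematics(config, schedule):
    diffs = []
    for seed in range(3):
        trajs = simulate_arena_cohort(AgentParams(seed=200 + seed), config,
                                      schedule)
        k = state_conditioned_kinematics(trajs, schedule, config)
        diffs.append(k["speed_change"])
    assert abs(np.mean(diffs)) < 0.15  # mm/s, ~1.5% of the mean speed


def test_state_never_occupied_is_nan(config, schedule):
    # a fly pinned deep in Q2 (lit only during epoch 1): during epoch 90-120 s
    # it is never lit
    frame0 = int(round(91.0 * config.frame_rate))
    n = 60
    x = -30 + 0.3 * np.arange(n)
    tr = Trajectory.from_positions("f0", x, np.full(n, 30.0), config,
                                   frame_start=frame0)
    from flyvalence.arena import Epoch, IlluminationSchedule

    sched = IlluminationSchedule(
        (Epoch(90.0, 120.0, frozenset({"Q1", "Q4"})),)
    )
    k = state_conditioned_kinematics([tr], sched, config)
    assert np.isnan(k["speed_lit"])
    assert not np.isnan(k["speed_unlit"])
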
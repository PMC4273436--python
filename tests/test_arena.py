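"""Arena geometry: quadrants, borders, choice zone, illumination and light field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flyvalence import (
    ArenaConfig,
    IlluminationSchedule,
    OutOfArenaError,
    Trajectory,
    assign_quadrant,
    border_distance,
    illumination_state,
    in_choice_zone,
    light_intensity,
)
from flyvalence.arena import Epoch, quadrant_codes


@pytest.mark.parametrize(
    "point,expected",
    [
        ((10, 10), "Q1"),
        ((-10, 10), "Q2"),
        ((10, -10), "Q3"),
        ((-10, -10), "Q4"),
        # axis ties: a zero coordinate counts as positive
        ((0, 0), "Q1"),
        ((0, 12), "Q1"),
        ((-12, 0), "Q2"),
        ((0, -12), "Q3"),
    ],
)
def test_quadrant_assignment(point, expected, config):
    assert assign_quadrant(point, config) == expected


def test_quadrant_partition_counts(config, rng):
    r = config.radius * np.sqrt(rng.random(1000))
    th = rng.uniform(-np.pi, np.pi, 1000)
    codes = quadrant_codes(r * np.cos(th), r * np.sin(th))
    counts = np.bincount(codes, minlength=5)[1:]
    assert counts.sum() == 1000
    assert np.all(counts > 0)


def test_point_outside_arena_raises(config):
    with pytest.raises(OutOfArenaError, match="radius"):
        assign_quadrant((60.0, 0.0), config)
    # inside the 1 mm jitter tolerance is accepted
    assert assign_quadrant((50.5, 0.0), config) == "Q1"


@pytest.mark.parametrize(
    "point,dist,border",
    [
        ((3, 20), 3.0, "vertical"),
        ((20, 3), 3.0, "horizontal"),
        ((4, 4), 4.0, "vertical"),  # tie resolves to the vertical border
        ((-3, 20), 3.0, "vertical"),
    ],
)
def test_border_distance(point, dist, border, config):
    d, b = border_distance(point, config)
    assert d == pytest.approx(dist)
    assert b == border


@pytest.mark.parametrize(
    "point,expected",
    [
        ((4, 30), True),
        ((4, 4), False),  # inside the center exclusion disk
        ((6, 30), False),
        ((-4.9, -20), True),
        ((0, 10), True),
    ],
)
def test_in_choice_zone_examples(point, expected, config):
    assert in_choice_zone(point, config) is expected


def test_choice_zone_matches_bruteforce_on_random_points(config, rng):
    r = config.radius * np.sqrt(rng.random(10_000))
    th = rng.uniform(-np.pi, np.pi, 10_000)
    x, y = r * np.cos(th), r * np.sin(th)
    expected = (np.minimum(np.abs(x), np.abs(y)) <= 5.0) & (np.hypot(x, y) >= 10.0)
    got = np.array([in_choice_zone((xi, yi), config) for xi, yi in zip(x, y)])
    assert np.array_equal(got, expected)


def test_border_distance_iff_choice_zone(config, rng):
    # distance <= 5 together with being outside the exclusion disk is exactly
    # the choice-zone membership
    r = config.radius * np.sqrt(rng.random(2000))
    th = rng.uniform(-np.pi, np.pi, 2000)
    for xi, yi in zip(r * np.cos(th), r * np.sin(th)):
        d, _ = border_distance((xi, yi), config)
        in_band = d <= config.choice_halfwidth and np.hypot(xi, yi) >= 10.0
        assert in_choice_zone((xi, yi), config) == in_band


@pytest.mark.parametrize(
    "point,t,expected",
    [
        ((-10, 10), 45.0, "lit"),  # Q2 during the first light-on epoch
        ((-10, 10), 15.0, "unlit"),  # no illumination 0-30 s
        ((10, 10), 100.0, "lit"),  # Q1 during the second light-on epoch
        ((10, 10), 45.0, "unlit"),
    ],
)
def test_illumination_state(point, t, expected, config, schedule):
    assert illumination_state(point, t, schedule, config) == expected


def test_time_outside_schedule_raises(config, schedule):
    with pytest.raises(ValueError, match="outside schedule"):
        illumination_state((10, 10), 130.0, schedule, config)


def test_light_intensity_ramp(config, schedule):
    # lit side: Q2 at t=45 s; distance from the vertical border is |x|
    assert light_intensity((-10, 30), 45, schedule, config) == pytest.approx(34.0)
    assert light_intensity((-1e-9, 30), 45, schedule, config) == pytest.approx(3.0)
    assert light_intensity((-5, 30), 45, schedule, config) == pytest.approx(18.5)
    assert light_intensity((-20, 30), 45, schedule, config) == pytest.approx(34.0)
    # unlit side and dark epochs are 0
    assert light_intensity((10, 30), 45, schedule, config) == 0.0
    assert light_intensity((-10, 30), 15, schedule, config) == 0.0


def test_light_intensity_monotone_continuous(config, schedule):
    ds = np.linspace(0, 25, 200)
    vals = [light_intensity((-d, 30), 45, schedule, config) for d in ds[ds > 0]]
    assert np.all(np.diff(vals) >= -1e-12)
    assert np.max(np.abs(np.diff(vals))) < 1.0  # no jumps on a fine grid


def test_schedule_validation():
    with pytest.raises(ValueError, match="contiguous"):
        IlluminationSchedule(
            (Epoch(0, 30, frozenset()), Epoch(40, 60, frozenset({"Q2", "Q3"})))
        )
    with pytest.raises(ValueError, match="diagonal"):
        Epoch(0, 30, frozenset({"Q1", "Q2"}))
    with pytest.raises(ValueError, match="t_start"):
        Epoch(30, 30, frozenset())


def test_default_schedule_matches_protocol(schedule):
    spans = [(e.t_start, e.t_end, set(e.lit)) for e in schedule.epochs]
    assert spans == [
        (0.0, 30.0, set()),
        (30.0, 60.0, {"Q2", "Q3"}),
        (60.0, 90.0, set()),
        (90.0, 120.0, {"Q1", "Q4"}),
    ]


@given(
    radius=st.floats(1, 200),
    half=st.floats(0.1, 0.9),
)
@settings(max_examples=25, deadline=None)
def test_config_invariants_hold_or_raise(radius, half):
    cfg = ArenaConfig(
        radius=radius,
        choice_halfwidth=half * radius,
        center_exclusion_radius=half * radius,
    )
    assert 0 < cfg.choice_halfwidth < cfg.radius


def test_config_rejects_bad_values():
    with pytest.raises(ValueError):
        ArenaConfig(radius=-1)
    with pytest.raises(ValueError):
        ArenaConfig(choice_halfwidth=60)
    with pytest.raises(ValueError):
        ArenaConfig(center_exclusion_radius=2)  # below choice_halfwidth
    with pytest.raises(ValueError):
        ArenaConfig(intensity_min_at_border=40)


def test_trajectory_rejects_disordered_frames():
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory("f", [0, 2, 2], [0, 1, 2], [0, 0, 0], [0, 0, 0])


def test_trajectory_bounds_error_names_fly_and_frame(config):
    tr = Trajectory("fly7", [0, 1], [0, 1 / 30], [0, 80.0], [0, 0])
    with pytest.raises(OutOfArenaError, match="fly7 frame 1"):
        tr.validate_bounds(config)
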
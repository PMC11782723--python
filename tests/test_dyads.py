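import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyadtrack.dyads import (
    ContactParams,
    approach_distance,
    contact_proportion,
    detect_social_contact,
    dyad_steps,
    mean_social_approach_velocity,
    weighted_social_approach_increment,
)

from _helpers import make_states, naive_dyad_summary, random_dyad

EAST, WEST, NORTH = 0.0, math.pi, math.pi / 2


class TestApproachDistance:
    def test_straight_approach_same_under_both_conventions(self):
        for conv in ("initial_partner_position", "current_partner_position"):
            assert approach_distance((0, 0), (0.5, 0), (2, 0), (2, 0), conv) == pytest.approx(0.5)

    def test_partner_motion_isolates_convention(self):
        # A stationary, B moves toward A: no approach credited to A under
        # the initial-position convention, full credit under the other.
        args = ((0, 0), (0, 0), (2, 0), (1, 0))
        assert approach_distance(*args, "initial_partner_position") == pytest.approx(0.0)
        assert approach_distance(*args, "current_partner_position") == pytest.approx(1.0)

    def test_moving_away_is_negative(self):
        v = approach_distance((0, 0), (0, 0.3), (1, 0), (1, 0))
        assert v == pytest.approx(1 - math.sqrt(1.09))
        assert v < 0


class TestWeightedIncrement:
    @pytest.mark.parametrize("theta_o,expected", [(0.0, 0.5), (45.0, 0.25), (90.0, 0.0)])
    def test_orientation_weight(self, theta_o, expected):
        # facing B and covering half the gap: increment = 0.5 · cos²θo
        assert weighted_social_approach_increment(0.5, 1.0, theta_o, 0.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_negative_approach_excluded(self):
        assert np.isnan(weighted_social_approach_increment(-0.1, 1.0, 0.0, 0.0))

    def test_zero_distance_excluded(self):
        assert np.isnan(weighted_social_approach_increment(0.1, 0.0, 0.0, 0.0))


def test_mean_social_approach_velocity():
    mean, n = mean_social_approach_velocity([0.5, 0.25])
    assert mean == pytest.approx(0.375) and n == 2
    mean, n = mean_social_approach_velocity([np.nan, np.nan])
    assert np.isnan(mean) and n == 0


class TestContact:
    def test_mutual_facing_within_band(self):
        assert detect_social_contact((0, 0), EAST, (1, 0), WEST)

    def test_below_distance_floor(self):
        assert not detect_social_contact((0, 0), EAST, (0.1, 0), WEST)

    def test_beyond_distance_ceiling(self):
        assert not detect_social_contact((0, 0), EAST, (2.5, 0), WEST)

    def test_partner_back_turned(self):
        assert not detect_social_contact((0, 0), EAST, (1, 0), EAST)

    def test_45_degree_boundary_inclusive(self):
        on = math.radians(45 - 1e-6)
        off = math.radians(45 + 1e-3)
        assert detect_social_contact((0, 0), on, (1, 0), WEST)
        assert not detect_social_contact((0, 0), off, (1, 0), WEST)
        assert detect_social_contact((0, 0), EAST, (0.2, 0), WEST)  # floor inclusive

    def test_symmetry(self, rng):
        for _ in range(200):
            pa, pb = rng.uniform(0, 3, 2), rng.uniform(0, 3, 2)
            ha, hb = rng.uniform(-np.pi, np.pi, 2)
            assert detect_social_contact(pa, ha, pb, hb) == detect_social_contact(pb, hb, pa, ha)


def test_contact_proportion_counts():
    in_contact = np.array([True] * 25 + [False] * 75)
    shared = np.ones(100, dtype=bool)
    prop, n_c, n_s = contact_proportion(in_contact, shared)
    assert prop == pytest.approx(0.25) and n_c == 25 and n_s == 100
    prop, _, _ = contact_proportion(np.array([False]), np.array([False]))
    assert np.isnan(prop)


def test_contact_proportion_manual_ten_step_stream():
    # B fixed at (1,0) facing west; A slides east from 0.05 to 0.95 facing east.
    ax = np.linspace(0.05, 0.95, 10)
    a = make_states(ax, np.zeros(10), np.full(10, EAST))
    b = make_states(np.ones(10), np.zeros(10), np.full(10, WEST))
    ds = dyad_steps(a, b)
    # hand count: in contact whenever distance 1-ax >= 0.2, i.e. ax <= 0.8 → 8 steps
    assert int(ds.in_contact.sum()) == 8
    prop, _, n_s = contact_proportion(ds.in_contact, ds.shared)
    assert n_s == 10 and prop == pytest.approx(0.8)


def test_dyad_steps_thetas_use_previous_bearing():
    # A at origin facing north at t=0, moves east toward B at (1,0)
    a = make_states([0.0, 0.5], [0.0, 0.0], [NORTH, NORTH])
    b = make_states([1.0, 1.0], [0.0, 0.0], [WEST, WEST])
    ds = dyad_steps(a, b)
    assert ds.theta_o[1] == pytest.approx(90.0)
    assert ds.theta_m[1] == pytest.approx(0.0)
    assert ds.approach[1] == pytest.approx(0.5)
    # cos²(90°) = 0: oriented away contributes nothing
    assert ds.weighted[1] == pytest.approx(0.0, abs=1e-20)


def test_zero_displacement_step_skipped():
    a = make_states([0.0, 0.0], [0.0, 0.0], [EAST, EAST])
    b = make_states([2.0, 1.0], [0.0, 0.0], [WEST, WEST])
    ds = dyad_steps(a, b)  # A did not move: theta_m undefined
    assert np.isnan(ds.weighted[1])


@given(st.floats(0.1, 10.0))
def test_weighted_increment_scale_covariant(k):
    """Scaling all coordinates by k leaves the increments unchanged."""
    rng = np.random.default_rng(7)
    a, b = random_dyad(rng, 80)
    base = dyad_steps(a, b).weighted
    a2 = make_states(a.x * k, a.y * k, a.heading, a.valid, pid="A")
    b2 = make_states(b.x * k, b.y * k, b.heading, b.valid, pid="B")
    scaled = dyad_steps(a2, b2, ContactParams(0.2 * k, 2.0 * k)).weighted
    np.testing.assert_allclose(scaled, base, atol=1e-10, equal_nan=True)


def test_increment_bounded_when_step_cannot_overshoot(rng):
    """With displacement ≤ distance_prev the increment lies in [0, 1]."""
    for _ in range(50):
        a, b = random_dyad(rng, 120)
        ds = dyad_steps(a, b)
        w = ds.weighted[~np.isnan(ds.weighted)]
        step = np.hypot(np.diff(a.x), np.diff(a.y))
        ok = step[~np.isnan(ds.weighted[1:])] <= ds.distance_prev[1:][~np.isnan(ds.weighted[1:])]
        assert np.all(w[ok] >= 0) and np.all(w[ok] <= 1.0 + 1e-12)


def test_contact_proportion_symmetric_between_directions(rng):
    a, b = random_dyad(rng, 300)
    ds_ab = dyad_steps(a, b)
    ds_ba = dyad_steps(b, a)
    np.testing.assert_array_equal(ds_ab.in_contact, ds_ba.in_contact)
    np.testing.assert_array_equal(ds_ab.shared, ds_ba.shared)


@pytest.mark.parametrize("convention", ["initial_partner_position", "current_partner_position"])
def test_vectorized_matches_naive_reference(rng, convention):
    """Dual-route check: vectorized pipeline vs pure-Python per-step loop."""
    for _ in range(10):
        a, b = random_dyad(rng, int(rng.integers(50, 400)))
        ds = dyad_steps(a, b, convention=convention)
        sav, n = mean_social_approach_velocity(ds.weighted)
        prop, _, n_s = contact_proportion(ds.in_contact, ds.shared)
        ref_sav, ref_n, ref_prop, ref_shared = naive_dyad_summary(a, b, convention=convention)
        assert n == ref_n and n_s == ref_shared
        if np.isnan(ref_sav):
            assert np.isnan(sav)
        else:
            assert sav == pytest.approx(ref_sav, abs=1e-12)
        assert prop == pytest.approx(ref_prop, abs=1e-12)
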
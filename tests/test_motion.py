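import math

import numpy as np
import pytest
from numpy.random import default_rng
from scipy import stats

import beeloop as bl
from beeloop.motion import (EXPLORATION, RETURN, BeeState, advance_state,
                            draw_switch_time, homing_angle, ou_update,
                            simulate_angular_speed, simulate_loop,
                            simulate_trip, target_angular_speed, wrap_angle)


class TestHomingAngle:
    @pytest.mark.parametrize("position,heading,expected", [
        ((10.0, 0.0), math.pi, 0.0),          # flying straight at the nest
        ((10.0, 0.0), 0.0, math.pi),          # flying straight away
        ((0.0, -10.0), 0.0, math.pi / 2),     # nest 90 degrees to the left
    ])
    def test_hand_geometry(self, position, heading, expected):
        assert homing_angle(position, heading, (0.0, 0.0)) == \
            pytest.approx(expected)

    def test_at_nest_is_undefined(self):
        with pytest.raises(ValueError):
            homing_angle((0.0, 0.0), 1.0, (0.0, 0.0))

    def test_signed_range_and_steering_direction(self):
        # phi in (-pi, pi]; turning by phi aligns the heading with the nest
        rng = default_rng(0)
        for _ in range(200):
            pos = rng.uniform(-100, 100, 2)
            heading = rng.uniform(-math.pi, math.pi)
            phi = homing_angle(pos, heading, (0.0, 0.0))
            assert -math.pi < phi <= math.pi
            bearing = math.atan2(-pos[1], -pos[0])
            assert float(wrap_angle(heading + phi)) == pytest.approx(bearing)


class TestTargetAngularSpeed:
    def test_zero_during_exploration(self, params):
        state = BeeState(position=(50.0, 20.0), heading=1.0,
                         angular_speed=0.3, phase=EXPLORATION)
        assert target_angular_speed(state, params, (0, 0)) == 0.0

    def test_proportional_to_homing_angle_during_return(self, params):
        # antipodal heading: phi = pi, omega* = eta* pi
        state = BeeState(position=(10.0, 0.0), heading=0.0,
                         angular_speed=0.0, phase=RETURN, switch_time=0.0)
        assert target_angular_speed(state, params, (0, 0)) == \
            pytest.approx(0.2 * math.pi)
        aligned = BeeState(position=(10.0, 0.0), heading=math.pi,
                           angular_speed=0.0, phase=RETURN, switch_time=0.0)
        assert target_angular_speed(aligned, params, (0, 0)) == pytest.approx(0.0)


class TestOUUpdate:
    def test_fixed_point(self, params):
        assert ou_update(0.0, 0.0, params, noise=0.0) == 0.0

    def test_deterministic_decay(self, params):
        # gamma = 1, dt = 0.01: omega decays by e^(-0.01) per step
        out = ou_update(1.0, 0.0, params, noise=0.0)
        assert out == pytest.approx(math.exp(-0.01), rel=1e-12)

    def test_transition_noise_scale(self, params):
        # empirical variance of the one-step noise matches
        # sigma^2 (1 - e^(-2 gamma dt)) / (2 gamma)
        rng = default_rng(7)
        draws = np.array([ou_update(0.0, 0.0, params, z)
                          for z in rng.standard_normal(20000)])
        expected = 0.37**2 * (1 - math.exp(-0.02)) / 2.0
        assert expected == pytest.approx(1.355e-3, rel=1e-2)
        assert draws.var() == pytest.approx(expected, rel=0.05)

    def test_stationary_variance(self, params, rng):
        # with omega* = 0 the long-run variance is sigma^2/(2 gamma)
        omega = simulate_angular_speed(params, n_steps=500_000, rng=rng,
                                       burn_in=10_000)
        target = params.omega_var
        n_eff = 500_000 * params.dt * 2 * params.gamma  # decorrelated count
        se = target * math.sqrt(2.0 / n_eff)
        assert abs(omega.var() - target) < 3 * se


class TestNoiseSpec:
    def test_child_streams_reproducible_and_distinct(self):
        from beeloop.motion import NoiseSpec
        spec_a = NoiseSpec(rng_seed=7)
        spec_b = NoiseSpec(rng_seed=7)
        assert spec_a.child_seed(3) == spec_b.child_seed(3)
        assert spec_a.child_seed(0) != spec_a.child_seed(1)
        assert 0 <= spec_a.child_seed(5) < 2**31
        x = spec_a.generator().standard_normal(4)
        y = spec_b.generator().standard_normal(4)
        np.testing.assert_array_equal(x, y)


class TestSwitchTime:
    def test_exponential_with_mean_alpha(self, params, rng):
        draws = draw_switch_time(params, rng, size=100_000)
        assert np.all(draws >= 0)
        assert draws.mean() == pytest.approx(30.0, abs=0.3)
        # CDF at the mean of an exponential is 1 - 1/e
        assert np.mean(draws <= 30.0) == pytest.approx(1 - math.exp(-1),
                                                       abs=0.01)


class TestAdvanceState:
    def test_ballistic_flight_without_noise(self, nest):
        p = bl.ModelParams(sigma=0.0)
        state = BeeState(position=(0.0, 0.0), heading=0.3, angular_speed=0.0,
                         switch_time=math.inf)
        for _ in range(100):
            state = advance_state(state, p, nest, noise=0.0)
        expected = 100 * p.speed * p.dt * np.array([math.cos(0.3),
                                                    math.sin(0.3)])
        np.testing.assert_allclose(state.position, expected, atol=1e-9)

    def test_constant_turning_traces_circle(self, nest):
        # impose omega = c each step: the path must stay on a circle of
        # radius v/|c| to within one step length
        p = bl.ModelParams(sigma=0.0)
        c = 0.5
        state = BeeState(position=(0.0, 0.0), heading=0.0, angular_speed=c,
                         switch_time=math.inf)
        centre = np.array([0.0, p.speed / c])  # left of initial velocity
        for _ in range(2000):
            state = advance_state(state, p, nest, noise=0.0)
            state.angular_speed = c
            r = np.hypot(*(state.position - centre))
            assert abs(r - p.speed / c) < p.speed * p.dt

    def test_step_displacement_is_speed_times_dt(self, params, nest, rng):
        state = BeeState(position=(0.0, 0.0), heading=0.0, angular_speed=0.0,
                         switch_time=5.0)
        for _ in range(500):
            new = advance_state(state, params, nest, rng.standard_normal())
            step = np.hypot(*(new.position - state.position))
            assert step == pytest.approx(params.speed * params.dt, abs=1e-9)
            assert -math.pi < new.heading <= math.pi
            state = new

    def test_phase_switch_is_one_way(self, params, nest, rng):
        state = BeeState(position=(0.0, 0.0), heading=0.0, angular_speed=0.0,
                         switch_time=0.05)
        phases = []
        for _ in range(20):
            state = advance_state(state, params, nest, rng.standard_normal())
            phases.append(state.phase)
        flip = phases.index(RETURN)
        assert all(ph == EXPLORATION for ph in phases[:flip])
        assert all(ph == RETURN for ph in phases[flip:])

    def test_rotational_symmetry_of_noise_free_dynamics(self, nest):
        # rotating the initial heading rotates the whole deterministic path
        p = bl.ModelParams(sigma=0.0)
        delta = 0.7

        def path(heading0):
            state = BeeState(position=(0.0, 0.0), heading=heading0,
                             angular_speed=0.0, switch_time=1.0)
            pts = []
            for _ in range(1500):
                state = advance_state(state, p, nest, noise=0.0)
                pts.append(state.position.copy())
            return np.array(pts)

        base = path(0.3)
        rotated = path(0.3 + delta)
        c, s = math.cos(-delta), math.sin(-delta)
        back = rotated @ np.array([[c, -s], [s, c]]).T
        np.testing.assert_allclose(back, base, atol=1e-8)


class TestSimulateLoop:
    def test_termination_contract(self, params, nest, rng):
        for _ in range(50):
            loop = simulate_loop(params, nest, rng)
            np.testing.assert_array_equal(loop.track.positions[0], nest)
            assert loop.track.times[-1] >= loop.switch_time or loop.censored
            if not loop.censored:
                assert np.hypot(*loop.track.positions[-1]) <= params.nest_radius

    def test_exact_speed_conservation(self, params, nest, rng):
        loop = simulate_loop(params, nest, rng)
        steps = np.hypot(*np.diff(loop.track.positions, axis=0).T)
        np.testing.assert_allclose(steps, params.speed * params.dt, atol=1e-9)

    def test_rarely_censored_with_homing(self, params, nest):
        rng = default_rng(99)
        censored = sum(simulate_loop(params, nest, rng).censored
                       for _ in range(300))
        assert censored <= 3  # termination in >=99% of loops

    def test_seed_reproducibility(self, params, nest):
        a = simulate_loop(params, nest, default_rng(5))
        b = simulate_loop(params, nest, default_rng(5))
        np.testing.assert_array_equal(a.track.positions, b.track.positions)
        assert a.switch_time == b.switch_time

    def test_dt_halving_preserves_extension_distribution(self, nest):
        # the OU update is exact, so halving dt only changes the path
        # between samples: loop extension distributions must agree
        from beeloop.observables import loop_extension
        exts = {}
        for dt in (0.01, 0.005):
            p = bl.ModelParams(dt=dt)
            rng = default_rng(31)
            exts[dt] = [loop_extension(simulate_loop(p, nest, rng), nest)
                        for _ in range(300)]
        ks = stats.ks_2samp(exts[0.01], exts[0.005])
        assert ks.pvalue > 0.01


class TestSimulateTrip:
    def test_records_every_step(self, params, nest, rng):
        track, returns = simulate_trip(params, nest, 900.0, rng)
        assert len(track) == 90_001
        assert track.sampling_interval == params.dt

    def test_loop_duration_never_below_switch_time(self, params, nest, rng):
        # first return cannot happen before the first switch time: check
        # via the slow reference stepper with an inspectable state
        track, returns = simulate_trip(params, nest, 300.0, rng)
        if len(returns):
            assert np.all(np.diff(np.concatenate([[0.0], returns])) > 0)

    def test_python_and_kernel_paths_agree_without_noise(self, nest):
        # sigma = 0, eta* = 0: deterministic ballistic flight; both paths
        # must produce the same straight line given the same heading
        p = bl.ModelParams(sigma=0.0, eta_star=0.0)
        track, _ = simulate_trip(p, nest, 10.0, default_rng(3))
        hooked, _ = simulate_trip(p, nest, 10.0, default_rng(3),
                                  stop_hook=lambda s: False)
        # same RNG consumption order: heading drawn first in both paths
        d_fast = np.hypot(*np.diff(track.positions, axis=0).T)
        d_slow = np.hypot(*np.diff(hooked.positions, axis=0).T)
        np.testing.assert_allclose(d_fast, p.speed * p.dt, atol=1e-9)
        np.testing.assert_allclose(d_slow, p.speed * p.dt, atol=1e-9)

    def test_stop_hook_truncates(self, params, nest, rng):
        track, _ = simulate_trip(params, nest, 100.0, rng,
                                 stop_hook=lambda s: s.clock >= 1.0)
        assert track.times[-1] < 100.0
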
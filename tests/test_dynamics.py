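"""Gillespie simulation, contact lifetimes, turnover and timescale calibration."""

from dataclasses import replace

import numpy as np
import pytest

from spinedyn import (
    build_generator,
    calibrate_timescale,
    contact_lifetimes,
    gillespie_run,
    occupancy_from_trajectory,
    solve_model,
    stationary_distribution,
    turnover_ratio,
)
from spinedyn import PlasticityParams, RateLaw, TraceParams


def constant_rate_params(m_rate=1.0, s_rate=1.0, q_rate=1.0, gamma=1.0):
    """Activity-independent model with unequal intrinsic-style rates.

    Uses flat (deep-plateau) laws so maturation/shrinkage/pruning take
    arbitrary constant values; pruning shares the shrinkage law, so only
    m = q = s or q = s configurations are exactly representable; tests
    needing q != s use delta shifts instead.
    """
    trace = TraceParams(lambda_resp=0.0)
    return PlasticityParams(
        maturation=RateLaw(m_rate, -1e6, "thin") if m_rate else RateLaw(0.0, 0.0, "thin"),
        shrinkage=RateLaw(s_rate, -1e6, "large") if s_rate else RateLaw(0.0, 0.0, "large"),
        delta=0.0,
        gamma=gamma,
        trace=trace,
    )


class TestGillespie:
    def test_absorbing_without_creation(self, intrinsic_params):
        params = replace(intrinsic_params, gamma=0.0)
        traj = gillespie_run(2, params, duration=100.0, seed=0)
        assert traj.events == ()

    def test_deterministic_given_seed(self, intrinsic_params):
        a = gillespie_run(2, intrinsic_params, duration=200.0, seed=9)
        b = gillespie_run(2, intrinsic_params, duration=200.0, seed=9)
        assert a.events == b.events

    def test_event_times_increase_and_transitions_valid(self, fixture_params):
        traj = gillespie_run(3, fixture_params, duration=50.0, seed=1)
        times = [t for t, _, _ in traj.events]
        assert all(b > a for a, b in zip(times, times[1:]))
        state = traj.initial_state
        steps = {
            "creation": (0, 1), "maturation": (1, -1),
            "shrinkage": (-1, 1), "pruning": (0, -1),
        }
        for _, kind, after in traj.events:
            da, di = steps[kind]
            assert after == (state[0] + da, state[1] + di)
            state = after

    def test_long_run_occupancy_near_uniform(self, intrinsic_params):
        traj = gillespie_run(1, intrinsic_params, duration=2e4, seed=3)
        occ = occupancy_from_trajectory(traj, burn_in=100.0)
        # SE of occupancy ~ sqrt(p(1-p) * 2*t_corr / T) with t_corr ~ 1
        se = np.sqrt((1 / 3) * (2 / 3) * 2.0 / 2e4)
        for state in [(0, 0), (0, 1), (1, 0)]:
            assert abs(occ[state] - 1 / 3) < 3 * se

    def test_rejects_bad_inputs(self, intrinsic_params):
        with pytest.raises(ValueError):
            gillespie_run(2, intrinsic_params, duration=-1.0)
        with pytest.raises(ValueError):
            gillespie_run(1, intrinsic_params, duration=1.0, initial_state=(2, 2))


class TestOccupancy:
    def test_point_mass_for_eventless_trajectory(self, intrinsic_params):
        params = replace(intrinsic_params, gamma=0.0)
        traj = gillespie_run(2, params, duration=10.0, seed=0)
        occ = occupancy_from_trajectory(traj)
        assert occ == {(0, 0): 1.0}

    def test_sums_to_one(self, fixture_params):
        traj = gillespie_run(2, fixture_params, duration=100.0, seed=4)
        occ = occupancy_from_trajectory(traj, burn_in=5.0)
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_burn_in_must_leave_a_window(self, intrinsic_params):
        traj = gillespie_run(1, intrinsic_params, duration=10.0, seed=0)
        with pytest.raises(ValueError):
            occupancy_from_trajectory(traj, burn_in=10.0)


class TestLifetimes:
    def test_constant_rate_closed_form(self, intrinsic_params):
        # m = q = s = 1: L_inactive = (1 + 1/1)/1 = 2, L_active = 1 + 2 = 3
        curves = contact_lifetimes(intrinsic_params, 3)
        for n in range(3):
            assert curves.inactive_by_na[n] == pytest.approx(2.0)
        for n in range(1, 4):
            assert curves.active_by_na[n] == pytest.approx(3.0)
        assert curves.averaged_inactive == pytest.approx(2.0)
        assert curves.averaged_active == pytest.approx(3.0)

    def test_fast_pruning_shortens_inactive_lifetime(self, intrinsic_params):
        fast = replace(intrinsic_params, delta=100.0)
        slow = contact_lifetimes(intrinsic_params, 2)
        quick = contact_lifetimes(fast, 2)
        assert quick.averaged_inactive < 0.05 * slow.averaged_inactive

    def test_matches_monte_carlo_first_passage(self, intrinsic_params):
        # single-contact chain with all rates 1: simulate time until pruning
        rng = np.random.default_rng(8)
        n_runs = 10_000
        lifetimes = np.empty(n_runs)
        for j in range(n_runs):
            t, state = 0.0, "inactive"
            while True:
                if state == "inactive":
                    t += rng.exponential(1.0 / 2.0)  # maturation + pruning
                    if rng.random() < 0.5:
                        state = "active"
                    else:
                        break
                else:
                    t += rng.exponential(1.0)  # shrinkage
                    state = "inactive"
            lifetimes[j] = t
        se = lifetimes.std() / np.sqrt(n_runs)
        curves = contact_lifetimes(intrinsic_params, 1)
        assert abs(lifetimes.mean() - curves.inactive_by_na[0]) < 3 * se

    def test_active_exceeds_inverse_shrinkage_rate(self, fixture_params):
        from spinedyn.rates import contact_rates

        curves = contact_lifetimes(fixture_params, 5)
        for n in range(1, 6):
            _, r_shr, _ = contact_rates(n, fixture_params)
            assert curves.active_by_na[n] > 1.0 / r_shr

    def test_cooperative_model_separates_lifetimes(self, fixture_params):
        """Active contacts outlive inactive ones when rates fall with activity."""
        curves = contact_lifetimes(fixture_params, 5)
        assert curves.averaged_active / curves.averaged_inactive > 1.0

    def test_zero_pruning_flags_infinite_lifetime(self):
        params = constant_rate_params(m_rate=1.0, s_rate=0.0)
        params = replace(params, shrinkage=RateLaw(0.0, 0.0, "large"))
        curves = contact_lifetimes(params, 2)
        assert curves.inactive_by_na[0] == np.inf


class TestTurnover:
    def test_gain_equals_loss_at_stationarity(self, fixture_params):
        a_dist = {3: 0.4, 5: 0.6}
        stat = solve_model(fixture_params, a_dist)
        report = turnover_ratio(fixture_params, stat)
        assert abs(report.gain_rate - report.loss_rate) < 1e-8

    def test_ratio_linear_in_window(self, intrinsic_params):
        stat = solve_model(intrinsic_params, {4: 1.0})
        r1 = turnover_ratio(intrinsic_params, stat, window=1.0)
        r2 = turnover_ratio(intrinsic_params, stat, window=2.0)
        assert r2.ratio == pytest.approx(2.0 * r1.ratio)

    def test_matches_gillespie_event_counting(self, intrinsic_params):
        stat = solve_model(intrinsic_params, {2: 1.0})
        report = turnover_ratio(intrinsic_params, stat, window=1.0)
        duration, burn = 2e4, 200.0
        traj = gillespie_run(2, intrinsic_params, duration=duration, seed=21)
        counts = [
            1 for t, kind, _ in traj.events
            if t > burn and kind in ("creation", "pruning")
        ]
        window = duration - burn
        observed_rate = len(counts) / window
        expected_rate = report.gain_rate + report.loss_rate
        se = np.sqrt(len(counts)) / window  # Poisson-scale error
        assert abs(observed_rate - expected_rate) < 3 * se

    def test_empty_synapse_rejected(self, intrinsic_params):
        params = replace(intrinsic_params, gamma=0.0)
        with pytest.warns(UserWarning):
            stat = solve_model(params, {2: 1.0})
        with pytest.raises(ValueError):
            turnover_ratio(params, stat)


class TestCalibration:
    def test_linear_scaling_arithmetic(self):
        from spinedyn.dynamics import TurnoverReport

        report = TurnoverReport(
            gain_rate=1.0, loss_rate=1.0, n_spines=10.0, ratio=0.1, window=1.0
        )
        assert calibrate_timescale(report, 0.2, 4.0) == pytest.approx(2.0)
        assert calibrate_timescale(report, 0.1, 1.0) == pytest.approx(1.0)
        assert calibrate_timescale(report, 0.4, 4.0) == pytest.approx(1.0)

    def test_rejects_nonpositive_target(self):
        from spinedyn.dynamics import TurnoverReport

        report = TurnoverReport(
            gain_rate=1.0, loss_rate=1.0, n_spines=10.0, ratio=0.1, window=1.0
        )
        with pytest.raises(ValueError):
            calibrate_timescale(report, 0.0, 4.0)
        with pytest.raises(ValueError):
            calibrate_timescale(report, 0.2, -1.0)
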
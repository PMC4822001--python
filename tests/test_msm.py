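"""MSM estimation: counting, reversible MLE, timescales, landscapes, seeds."""

import numpy as np
import pytest

from conformakin import msm as M
from conformakin.synthetic import (DoubleWell1D, brownian_dynamics,
                                   sample_markov_chain, stationary_distribution)


class TestCountTransitions:
    def test_direct_enumeration_lag_one(self):
        c = M.count_transitions([np.array([0, 0, 1, 1, 0, 1])], lag=1)
        assert c.counts.tolist() == [[1, 2], [1, 1]]
        assert c.counts.sum() == 5

    def test_single_pair_at_maximal_lag(self):
        c = M.count_transitions([np.arange(6) % 2], lag=5)
        assert c.counts.sum() == 1

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 5, size=10_000)
        lag = 7
        c = M.count_transitions([d], lag=lag)
        brute = np.zeros((5, 5))
        for t in range(len(d) - lag):
            brute[d[t], d[t + lag]] += 1
        assert np.array_equal(c.counts, brute)

    def test_no_cross_trajectory_pairs(self):
        c = M.count_transitions([np.array([0, 0]), np.array([1, 1])], lag=1)
        assert c.counts[0, 1] == 0 and c.counts[1, 0] == 0

    def test_all_trajectories_shorter_than_lag_error(self):
        with pytest.raises(ValueError, match="lag"):
            M.count_transitions([np.array([0, 1])], lag=5)


class TestEstimate:
    def test_disconnected_states_trimmed_to_larger_count_component(self):
        counts = M.CountMatrix(np.array([[5.0, 0.0], [0.0, 7.0]]), lag=1,
                               total_frames=14)
        res = M.MarkovStateModel(counts, lag=1).fit()
        assert res.active_set.tolist() == [1]
        assert res.T.tolist() == [[1.0]]

    def test_symmetric_counts_fixed_point(self):
        counts = M.CountMatrix(np.array([[8.0, 2.0], [2.0, 8.0]]), lag=1,
                               total_frames=20)
        res = M.MarkovStateModel(counts, lag=1).fit()
        assert np.allclose(res.T, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)
        assert np.allclose(res.pi, [0.5, 0.5], atol=1e-10)

    def test_three_state_parameter_recovery(self, three_state_T):
        d = sample_markov_chain(three_state_T, 10 ** 6, start="stationary", seed=21)
        res = M.MarkovStateModel([d], lag=1).fit()
        assert np.max(np.abs(res.T - three_state_T)) < 0.01
        pi_true = stationary_distribution(three_state_T)
        assert np.max(np.abs(res.pi - pi_true)) < 0.01

    def test_detailed_balance_holds(self, two_state_T):
        d = sample_markov_chain(two_state_T, 100_000, start=0, seed=22)
        res = M.MarkovStateModel([d], lag=2).fit()
        assert res.detailed_balance_residual() < 1e-8

    def test_eigenvalue_modulus_bounded(self, three_state_T):
        d = sample_markov_chain(three_state_T, 50_000, start=0, seed=23)
        res = M.MarkovStateModel([d], lag=1).fit()
        assert np.all(np.abs(res.eigenvalues) <= 1 + 1e-10)
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)

    def test_chapman_kolmogorov_on_markovian_data(self, two_state_T):
        d = sample_markov_chain(two_state_T, 500_000, start="stationary", seed=24)
        t1 = M.MarkovStateModel([d], lag=1).fit()
        t2 = M.MarkovStateModel([d], lag=2).fit()
        assert np.max(np.abs(t1.T @ t1.T - t2.T)) < 0.01

    def test_nonreversible_fallback_is_naive_symmetrization(self):
        counts = M.CountMatrix(np.array([[6.0, 4.0], [2.0, 8.0]]), lag=1,
                               total_frames=20)
        res = M.MarkovStateModel(counts, lag=1, reversible=False).fit()
        s = np.array([[6.0, 3.0], [3.0, 8.0]])
        assert np.allclose(res.T, s / s.sum(axis=1, keepdims=True))


class TestImpliedTimescales:
    def test_log_unit_eigenvalue(self):
        ts = M.implied_timescales(np.array([1.0, np.exp(-1.0)]), lag_time=15.0)
        assert ts[0] == pytest.approx(15.0, abs=1e-10)

    def test_half_eigenvalue_closed_form(self):
        ts = M.implied_timescales(np.array([1.0, 0.5]), lag_time=20.0)
        assert ts[0] == pytest.approx(-20.0 / np.log(0.5), abs=1e-10)
        assert ts[0] == pytest.approx(28.8539, abs=1e-4)

    def test_near_unit_eigenvalue_is_infinite(self):
        ts = M.implied_timescales(np.array([1.0, 1.0 - 1e-13]), lag_time=1.0)
        assert np.isinf(ts[0])

    def test_negative_eigenvalue_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            ts = M.implied_timescales(np.array([1.0, -0.2]), lag_time=1.0)
        assert np.isnan(ts[0])


class TestLagScan:
    def test_markovian_data_flat_and_smallest_lag_suggested(self, two_state_T):
        d = sample_markov_chain(two_state_T, 400_000, start="stationary", seed=30)
        lags = [1, 2, 3, 5, 8]
        table, suggested = M.lag_scan([d], lags)
        assert suggested == 1
        t_ref = table[1][0]
        for lag in lags:
            assert abs(table[lag][0] - t_ref) / t_ref < 0.1

    def test_hidden_two_state_plateau_matches_relaxation_time(self):
        # hidden 2-state chain observed through a noisy 4-state discretization:
        # timescales rise then plateau at the hidden relaxation time
        a, b = 0.02, 0.04
        T = np.array([[1 - a, a], [b, 1 - b]])
        rng = np.random.default_rng(31)
        hidden = sample_markov_chain(T, 2_000_000, start="stationary", seed=31)
        # each hidden state splits into two observed substates, 10% misassigned
        obs = 2 * hidden + rng.integers(0, 2, size=len(hidden))
        flip = rng.random(len(hidden)) < 0.05
        obs[flip] = 3 - obs[flip]  # crosses the hidden boundary
        t_true = -1.0 / np.log(1 - a - b)
        table, suggested = M.lag_scan([obs], [1, 5, 10, 20, 40, 60, 80],
                                      n_timescales=1)
        assert table[1][0] < table[40][0]  # rises out of the discretization error
        assert abs(table[40][0] - t_true) / t_true < 0.10
        assert suggested is not None

    def test_fewer_than_three_lags_error(self):
        with pytest.raises(ValueError, match="3 lags"):
            M.lag_scan([np.zeros(10, dtype=int)], [1])


class TestFreeEnergySurface:
    def test_single_state_uniform_histogram_flat(self):
        res = _results_T(np.array([[1.0]]), np.array([1.0]))
        obs = np.linspace(0.05, 0.95, 1000) % 1.0
        grid = M.free_energy_surface(res, obs, np.zeros(1000, dtype=int), bins=10)
        assert np.nanmax(np.abs(grid.F)) < 1e-10

    def test_two_delta_states_give_kt_ln4(self):
        T = np.array([[0.9, 0.1], [0.4, 0.6]])  # pi = (0.8, 0.2)
        res = _results_T(T, np.array([0.8, 0.2]))
        obs = np.array([0.25] * 10 + [0.75] * 10)
        assign = np.array([0] * 10 + [1] * 10)
        grid = M.free_energy_surface(res, obs, assign, bins=2, kT=1.0)
        occupied = grid.F[np.isfinite(grid.F)]
        assert np.max(occupied) == pytest.approx(np.log(4.0), abs=1e-12)

    def test_double_well_fixture_recovers_potential(self):
        h = 2.0
        pot = DoubleWell1D(h)
        x = brownian_dynamics(pot, dt=1e-3, n_steps=2_000_000, seed=33)
        # 2-state MSM on the sign of x
        d = (x > 0).astype(int)
        res = M.MarkovStateModel([d[::10]], lag=5).fit()
        kT = M.KT_298K
        grid = M.free_energy_surface(res, x[::10], d[::10], bins=40, kT=kT)
        centers = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        f_ref = kT * pot.beta_u(centers)
        well = np.abs(np.abs(centers) - 1.0) < 0.4
        delta = grid.F[well] - f_ref[well]
        # match up to an additive constant within the wells
        assert np.nanmax(delta - np.nanmean(delta)) < 0.15

    def test_state_without_frames_errors(self):
        res = _results_T(np.array([[0.5, 0.5], [0.5, 0.5]]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="state 1"):
            M.free_energy_surface(res, np.zeros(5), np.zeros(5, dtype=int), bins=2)

    def test_2d_probability_sums_to_one(self):
        T = np.array([[0.9, 0.1], [0.4, 0.6]])
        res = _results_T(T, np.array([0.8, 0.2]))
        rng = np.random.default_rng(34)
        obs = rng.normal(size=(100, 2))
        assign = rng.integers(0, 2, size=100)
        grid = M.free_energy_surface(res, obs, assign, bins=5)
        assert grid.probability.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmin(grid.F) == 0.0


def _results_T(T, pi):
    vals = np.sort(np.real(np.linalg.eigvals(T)))[::-1]
    return M.MSMResults(T=T, pi=pi, eigenvalues=vals, lag=1, frame_spacing=1.0,
                        active_set=np.arange(T.shape[0]))


class TestAdaptiveSeeds:
    def test_lowest_population_selected(self):
        assert M.adaptive_seed_states(np.array([0.5, 0.3, 0.2]), 1).tolist() == [2]

    def test_all_states_sorted_ascending(self):
        pi = np.array([0.5, 0.2, 0.3])
        assert M.adaptive_seed_states(pi, 3).tolist() == [1, 2, 0]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(35)
        pi = rng.dirichlet(np.ones(100))
        got = M.adaptive_seed_states(pi, 10)
        oracle = np.argsort(pi, kind="stable")[:10]
        assert got.tolist() == oracle.tolist()

    def test_ties_broken_by_index(self):
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        assert M.adaptive_seed_states(pi, 2).tolist() == [0, 1]

    def test_n_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            M.adaptive_seed_states(np.array([1.0]), 2)


class TestSerialization:
    def test_round_trip_revalidates(self, two_state_T, tmp_path):
        d = sample_markov_chain(two_state_T, 20_000, start=0, seed=40)
        res = M.MarkovStateModel([d], lag=1, frame_spacing=0.1).fit()
        p = tmp_path / "msm.npz"
        res.save(p)
        back = M.MSMResults.load(p)
        assert np.array_equal(back.T, res.T)
        assert np.array_equal(back.pi, res.pi)
        assert back.lag_time == res.lag_time
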
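"""Count/transition/rate matrix estimation and spectral analysis."""

import numpy as np
import pytest
import scipy.linalg

from hbfold import (
    CountMatrix,
    MicrostateTrajectory,
    RateMatrix,
    SimulationRecipe,
    TransitionMatrix,
    count_transitions,
    implied_timescale_scan,
    rate_matrix_from_transition,
    rate_standard_errors,
    relaxation_times,
    simulate_ctmc,
    stationary_distribution,
    symmetrize_counts,
    transition_matrix,
)
from hbfold.kinetics import LagError, ReducibleGeneratorError, UnvisitedStateError


def _traj(states, dt=1.0, maxhb=None):
    states = np.asarray(states)
    return MicrostateTrajectory(
        states=states, dt=dt, maxhb=states.max() if maxhb is None else maxhb
    )


class TestCounting:
    def test_enumerated_alternating_sequence(self):
        c = count_transitions(_traj([0, 1, 0, 1]), lag=1.0)
        assert c.counts[1, 0] == 2
        assert c.counts[0, 1] == 1
        assert np.trace(c.counts) == 0
        assert c.n_windows == 3

    def test_constant_trajectory_counts_diagonal(self):
        c = count_transitions(_traj([2, 2, 2, 2], maxhb=3), lag=2.0)
        assert c.counts[2, 2] == 2
        assert c.counts.sum() == c.n_windows == 2

    def test_multiple_trajectories_pool_without_crossing(self):
        t1, t2 = _traj([0, 1], maxhb=1), _traj([1, 0], maxhb=1)
        c = count_transitions([t1, t2], lag=1.0)
        assert c.counts[1, 0] == 1 and c.counts[0, 1] == 1
        assert c.n_windows == 2

    def test_lag_validation(self):
        with pytest.raises(LagError):
            count_transitions(_traj([0, 1, 0]), lag=0.5)
        with pytest.raises(LagError):
            count_transitions(_traj([0, 1, 0]), lag=5.0)


class TestSymmetrize:
    def test_average_with_transpose_and_conservation(self):
        c = CountMatrix(counts=np.array([[0.0, 4.0], [2.0, 0.0]]), lag=1.0, n_windows=6)
        s = symmetrize_counts(c)
        assert s.counts.tolist() == [[0, 3], [3, 0]]
        assert s.counts.sum() == c.counts.sum()
        again = symmetrize_counts(s)
        np.testing.assert_array_equal(again.counts, s.counts)


class TestTransitionMatrix:
    def test_column_normalisation(self):
        c = CountMatrix(counts=np.array([[3.0, 1.0], [1.0, 3.0]]), lag=1.0, n_windows=8)
        T = transition_matrix(c)
        np.testing.assert_allclose(T.T, [[0.75, 0.25], [0.25, 0.75]])

    def test_unvisited_state_is_named(self):
        c = CountMatrix(
            counts=np.array([[1.0, 0.0], [0.0, 0.0]]), lag=1.0, n_windows=1
        )
        with pytest.raises(UnvisitedStateError, match="1"):
            transition_matrix(c)

    def test_random_counts_give_stochastic_columns(self):
        rng = np.random.default_rng(7)
        c = CountMatrix(counts=rng.random((5, 5)) + 0.01, lag=1.0, n_windows=1)
        T = transition_matrix(c)
        np.testing.assert_allclose(T.T.sum(axis=0), 1.0, atol=1e-12)


class TestRateMatrix:
    def test_roundtrip_recovers_generator(self, ala5_K):
        T = TransitionMatrix(T=scipy.linalg.expm(ala5_K.K / 1e3 * 2.0), lag=2.0)
        K = rate_matrix_from_transition(T)
        np.testing.assert_allclose(K.K, ala5_K.K, rtol=1e-6, atol=1e-6)

    def test_identity_maps_to_zero_generator(self):
        K = rate_matrix_from_transition(TransitionMatrix(T=np.eye(3), lag=1.0))
        np.testing.assert_allclose(K.K, 0.0, atol=1e-9)

    def test_two_state_closed_form_logarithm(self):
        T = TransitionMatrix(T=np.array([[0.9, 0.1], [0.1, 0.9]]), lag=1.0)
        K = rate_matrix_from_transition(T)
        expected_ns = np.log(0.8) / (-2.0)  # ns^-1
        assert K.K[1, 0] / 1e3 == pytest.approx(expected_ns, rel=1e-10)

    def test_generator_validity_enforced(self):
        rng = np.random.default_rng(3)
        M = rng.random((4, 4)) + np.eye(4)
        T = TransitionMatrix(T=M / M.sum(axis=0), lag=1.0)
        K = rate_matrix_from_transition(T).K
        off = K[~np.eye(4, dtype=bool)]
        assert off.min() >= 0
        np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-9)


class TestStationary:
    def test_reference_four_state_distribution(self, ala5_K, ala5_p):
        np.testing.assert_allclose(
            ala5_p.p, [0.9363, 0.0404, 0.0115, 0.0117], atol=5e-4
        )
        # agrees with the independently tabulated coil pattern population
        assert ala5_p.p[0] == pytest.approx(0.934696, rel=5e-3)

    def test_symmetric_two_state_is_uniform(self):
        K = RateMatrix(K=np.array([[-1.0, 1.0], [1.0, -1.0]]))
        np.testing.assert_allclose(stationary_distribution(K).p, 0.5)

    def test_detailed_balance_residual_small(self, ala5_K, ala5_p):
        """Printed rates and populations nearly satisfy k_ij p_j = k_ji p_i."""
        K, p = ala5_K.K, ala5_p.p
        for i in range(4):
            for j in range(i + 1, 4):
                fwd, bwd = K[i, j] * p[j], K[j, i] * p[i]
                assert abs(fwd - bwd) / ((fwd + bwd) / 2) < 0.05

    def test_reducible_generator_reported(self):
        K = RateMatrix(
            K=np.array(
                [
                    [-1.0, 1.0, 0.0, 0.0],
                    [1.0, -1.0, 0.0, 0.0],
                    [0.0, 0.0, -2.0, 2.0],
                    [0.0, 0.0, 2.0, -2.0],
                ]
            )
        )
        with pytest.raises(ReducibleGeneratorError, match=r"\[0, 1\]"):
            stationary_distribution(K)


def _char_poly_coeffs(K):
    """Faddeev-LeVerrier recursion: eigensolver-independent oracle."""
    n = K.shape[0]
    coeffs = [1.0]
    M = np.zeros_like(K)
    for k in range(1, n + 1):
        M = K @ M + coeffs[-1] * np.eye(n)
        coeffs.append(-np.trace(K @ M) / k)
    return np.array(coeffs)


class TestRelaxationTimes:
    def test_four_state_slowest_matches_characteristic_cubic(self, ala5_K):
        taus = relaxation_times(ala5_K)
        # remove the exact-zero root analytically, then solve the cubic
        coeffs = _char_poly_coeffs(ala5_K.K)
        cubic = np.polynomial.polynomial.polyroots(coeffs[:-1][::-1])
        slowest_rate = -np.max(cubic.real)  # μs^-1
        assert slowest_rate == pytest.approx(299.75, abs=0.1)
        assert taus[0] == pytest.approx(1e3 / slowest_rate, rel=1e-9)
        assert taus[0] == pytest.approx(3.3, abs=0.05)

    def test_seven_state_slowest(self, ala8_K):
        assert relaxation_times(ala8_K)[0] == pytest.approx(33.0, abs=0.5)

    def test_two_state_closed_form(self):
        a, b = 0.7, 1.8
        K = RateMatrix(K=np.array([[-a, b], [a, -b]]))
        taus = relaxation_times(K)
        assert len(taus) == 1
        assert taus[0] == pytest.approx(1e3 / (a + b), rel=1e-12)

    def test_relabeling_and_time_rescaling_invariance(self, ala5_K):
        taus = relaxation_times(ala5_K)
        perm = np.array([2, 0, 3, 1])
        shuffled = RateMatrix(K=ala5_K.K[np.ix_(perm, perm)])
        np.testing.assert_allclose(relaxation_times(shuffled), taus, rtol=1e-9)
        doubled = RateMatrix(K=2.0 * ala5_K.K)
        np.testing.assert_allclose(relaxation_times(doubled), taus / 2, rtol=1e-9)


class TestParameterRecovery:
    def test_ctmc_estimates_within_three_se(self, ala5_K, ala5_sim):
        """Window-count estimation recovers the generating rates."""
        c = count_transitions(ala5_sim, 2.0)
        K_est = rate_matrix_from_transition(transition_matrix(c)).K
        se = rate_standard_errors(c)
        off = ~np.eye(4, dtype=bool)
        strong = (ala5_K.K >= 2.0) & off
        dev = np.abs(K_est - ala5_K.K) / se
        assert np.nanmax(dev[strong]) < 3.0

    def test_implied_timescales_flat_for_markovian_input(self):
        K = RateMatrix(K=np.array([[-20.0, 30.0], [20.0, -30.0]]))  # τ = 20 ns
        traj = simulate_ctmc(
            SimulationRecipe(rate_matrix=K, duration=40000.0, dt=0.1, seed=5)
        )
        scan = implied_timescale_scan(traj, [1.0, 2.0, 5.0, 10.0])
        taus = scan["slowest_tau_ns"].to_numpy()
        assert np.all(np.abs(taus - 20.0) / 20.0 < 0.15)
        assert taus.std() / taus.mean() < 0.1

    def test_deterministic_alternation_hits_resolution_floor(self):
        traj = _traj([0, 1] * 50, dt=1.0, maxhb=1)
        scan = implied_timescale_scan(traj, [1.0])
        # period-2 flipping has no slow mode: τ at or below the lag
        assert scan["slowest_tau_ns"].iloc[0] <= 1.0
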
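"""Flux networks, free-energy profiles and widest folding paths."""

import itertools

import numpy as np
import pytest

from hbfold import (
    KineticNetwork,
    RateMatrix,
    StationaryDistribution,
    flux_weights,
    free_energy_profile,
    gmwp,
    max_bottleneck_path,
    stationary_distribution,
)
from hbfold.network import NoPathError


def brute_force_widest(W, s, t):
    """Exhaustive widest-path search over all simple paths."""
    n = W.shape[0]
    best = (-1.0, None)
    others = [x for x in range(n) if x not in (s, t)]
    for L in range(n - 1):
        for mid in itertools.permutations(others, L):
            path = (s,) + mid + (t,)
            if any(W[a, b] <= 0 for a, b in zip(path[:-1], path[1:])):
                continue
            b = min(W[a, b] for a, b in zip(path[:-1], path[1:]))
            if b > best[0]:
                best = (b, path)
    return best


class TestFluxWeights:
    def test_reference_four_state_fluxes(self, ala5_K, ala5_p):
        net = flux_weights(ala5_K, ala5_p)
        assert net.weights[0, 1] == pytest.approx(15.16, abs=0.02)
        assert net.weights[0, 3] == pytest.approx(2.43, abs=0.01)

    def test_detailed_balance_input_gives_equal_terms(self):
        K = RateMatrix(K=np.array([[-1.0, 2.0], [1.0, -2.0]]))
        p = stationary_distribution(K)
        net = flux_weights(K, p)
        assert net.weights[0, 1] == pytest.approx(K.K[0, 1] * p.p[1], rel=1e-12)

    def test_flux_homogeneous_in_populations(self, ala5_K, ala5_p):
        net = flux_weights(ala5_K, ala5_p)
        # scaling all rates scales all weights identically
        net2 = flux_weights(RateMatrix(K=3.0 * ala5_K.K), ala5_p)
        np.testing.assert_allclose(net2.weights, 3.0 * net.weights, rtol=1e-12)


class TestFreeEnergyProfile:
    def test_equal_populations_are_degenerate(self):
        np.testing.assert_allclose(free_energy_profile(np.array([0.5, 0.5])), 0.0)
        np.testing.assert_allclose(free_energy_profile(np.full(5, 0.2)), 0.0)

    def test_nine_to_one_ratio(self):
        dG = free_energy_profile(np.array([0.9, 0.1]), temperature=298.0)
        assert dG[0] == 0.0
        assert dG[1] == pytest.approx(-0.0019872 * 298.0 * np.log(1 / 9), rel=1e-12)
        assert dG[1] == pytest.approx(1.301, abs=1e-3)

    def test_zero_population_marked_absent(self):
        dG = free_energy_profile(np.array([0.7, 0.3, 0.0]))
        assert np.isnan(dG[2])


class TestWidestPath:
    def test_triangle_detour_beats_direct_edge(self):
        W = np.zeros((3, 3))
        W[0, 2] = W[2, 0] = 1.0  # s - t
        W[0, 1] = W[1, 0] = 3.0  # s - m
        W[1, 2] = W[2, 1] = 2.0  # m - t
        res = max_bottleneck_path(KineticNetwork(weights=W), 0, 2)
        assert res.path == (0, 1, 2)
        assert res.bottleneck_weight == 2.0

    def test_two_node_graph(self):
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        res = gmwp(KineticNetwork(weights=W), 0, 1)
        assert res.path == (0, 1)
        assert res.bottleneck_edge == (0, 1)

    def test_disconnected_endpoints_raise(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(NoPathError):
            max_bottleneck_path(KineticNetwork(weights=W), 0, 3)

    def test_four_state_direct_folding_path(self, ala5_K, ala5_p):
        """The four-state flux network folds directly, coil -> helix."""
        net = flux_weights(ala5_K, ala5_p)
        res = gmwp(net, 0, 3)
        assert res.path == (0, 3)
        assert res.bottleneck_edge == (0, 3)

    def test_seven_state_single_intermediate(self, ala8_K, ala8_p):
        """The seven-state network folds 0 -> 4 -> 6 with bottleneck 0-4."""
        net = flux_weights(ala8_K, ala8_p)
        res = gmwp(net, 0, 6)
        assert res.path == (0, 4, 6)
        assert set(res.bottleneck_edge) == {0, 4}
        assert res.bottleneck_weight < net.weights[4, 6]

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n = int(rng.integers(4, 9))
            W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.6), 1)
            W = W + W.T
            net = KineticNetwork(weights=W)
            expected = brute_force_widest(W, 0, n - 1)
            if expected[1] is None:
                with pytest.raises(NoPathError):
                    max_bottleneck_path(net, 0, n - 1)
                continue
            res = max_bottleneck_path(net, 0, n - 1)
            assert res.bottleneck_weight == pytest.approx(expected[0], rel=1e-12)
            g = gmwp(net, 0, n - 1)
            assert g.bottleneck_weight == pytest.approx(expected[0], rel=1e-12)

    def test_every_subpath_of_gmwp_is_widest(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(5, 9))
            W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.7), 1)
            W = W + W.T
            net = KineticNetwork(weights=W)
            try:
                res = gmwp(net, 0, n - 1)
            except NoPathError:
                continue
            path = res.path
            assert len(set(path)) == len(path)  # simple
            for i in range(len(path) - 1):
                for j in range(i + 1, len(path)):
                    sub = path[i:j + 1]
                    b = min(W[a, c] for a, c in zip(sub[:-1], sub[1:]))
                    best, _ = brute_force_widest(W, sub[0], sub[-1])
                    assert b == pytest.approx(best, rel=1e-12)

    def test_monotone_weight_transform_preserves_path(self, ala8_K, ala8_p):
        net = flux_weights(ala8_K, ala8_p)
        res = gmwp(net, 0, 6)
        transformed = KineticNetwork(weights=np.sqrt(net.weights))
        res2 = gmwp(transformed, 0, 6)
        assert res2.path == res.path

    def test_gmwp_bottleneck_matches_mwp_bottleneck(self, ala8_K, ala8_p):
        net = flux_weights(ala8_K, ala8_p)
        assert gmwp(net, 0, 6).bottleneck_weight == pytest.approx(
            max_bottleneck_path(net, 0, 6).bottleneck_weight, rel=1e-12
        )

    def test_population_scaling_is_monotone_transform(self, ala5_K, ala5_p):
        net = flux_weights(ala5_K, ala5_p)
        scaled = KineticNetwork(weights=net.weights * 7.5)
        assert gmwp(scaled, 0, 3).path == gmwp(net, 0, 3).path
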
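"""Graph measures vs brute-force oracles; thresholding; cost correction."""

import numpy as np
import pytest

from neoconn.io import Connectome
from neoconn.metrics import (
    cost_corrected_features,
    default_density_grid,
    density,
    global_efficiency,
    nodal_degree,
    nodal_efficiency,
    nodal_strength,
    proportional_threshold,
    shortest_path_lengths,
)

import oracles
from conftest import random_connectome


class TestDensity:
    def test_complete_graph(self):
        n = 93
        w = np.ones((n, n)) - np.eye(n)
        assert density(Connectome("s", w, [str(i) for i in range(n)])) == 1.0

    def test_empty_graph(self):
        assert density(Connectome("s", np.zeros((5, 5)), list("abcde"))) == 0.0

    def test_three_of_six_pairs(self):
        w = np.zeros((4, 4))
        for i, j in ((0, 1), (1, 2), (2, 3)):
            w[i, j] = w[j, i] = 1.0
        assert density(Connectome("s", w, list("abcd"))) == 0.5


class TestStrength:
    def test_single_edge(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        s = nodal_strength(Connectome("s", w, list("abcd")))
        np.testing.assert_array_equal(s, [2, 2, 0, 0])

    def test_complete_unit_graph(self):
        n = 7
        w = np.ones((n, n)) - np.eye(n)
        s = nodal_strength(Connectome("s", w, [str(i) for i in range(n)]))
        np.testing.assert_array_equal(s, np.full(n, n - 1))

    def test_matches_row_sum_oracle(self, rng):
        c = random_connectome(rng, 10)
        np.testing.assert_allclose(nodal_strength(c), oracles.strengths(c.weights))

    def test_sums_to_twice_total_weight(self, rng):
        c = random_connectome(rng, 12)
        assert nodal_strength(c).sum() == pytest.approx(c.weights.sum())


class TestShortestPaths:
    def test_inverse_weight_lengths(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 2.0
        d = shortest_path_lengths(Connectome("s", w, list("ab")))
        assert d[0, 1] == 0.5

    def test_two_hop_path(self, path3):
        d = shortest_path_lengths(path3)
        assert d[0, 2] == 2.0

    def test_disconnected_pair_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = shortest_path_lengths(Connectome("s", w, list("abc")))
        assert np.isinf(d[0, 2])

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            c = random_connectome(rng, n, density=float(rng.uniform(0.2, 0.9)))
            np.testing.assert_allclose(
                shortest_path_lengths(c), oracles.floyd_warshall(c.weights)
            )


class TestEfficiencies:
    def test_complete_unit_graph_global_efficiency_one(self):
        n = 6
        w = np.ones((n, n)) - np.eye(n)
        assert global_efficiency(
            Connectome("s", w, [str(i) for i in range(n)])
        ) == pytest.approx(1.0)

    def test_empty_graph_zero(self):
        assert global_efficiency(Connectome("s", np.zeros((4, 4)), list("abcd"))) == 0.0

    def test_path3_five_sixths(self, path3):
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_triangle_nodal_efficiency_one(self, triangle):
        np.testing.assert_allclose(nodal_efficiency(triangle), np.ones(3))

    def test_star_center_zero(self):
        n = 5
        w = np.zeros((n, n))
        for leaf in range(1, n):
            w[0, leaf] = w[leaf, 0] = 1.0
        eff = nodal_efficiency(Connectome("s", w, [str(i) for i in range(n)]))
        assert eff[0] == 0.0  # leaves share no edges
        assert (eff[1:] == 0.0).all()  # each leaf has a single neighbour

    def test_global_matches_brute_force(self, rng):
        for _ in range(20):
            c = random_connectome(rng, int(rng.integers(3, 9)))
            assert global_efficiency(c) == pytest.approx(
                oracles.efficiency(c.weights)
            )

    def test_nodal_matches_brute_force_neighbourhoods(self, rng):
        c = random_connectome(rng, 8, density=0.6)
        eff = nodal_efficiency(c)
        for v in range(8):
            nbrs = np.flatnonzero(c.weights[v] > 0)
            if nbrs.size < 2:
                assert eff[v] == 0.0
            else:
                sub = c.weights[np.ix_(nbrs, nbrs)]
                assert eff[v] == pytest.approx(oracles.efficiency(sub))


class TestProportionalThreshold:
    def test_keeps_three_largest_of_six(self, rng):
        w = np.zeros((4, 4))
        vals = [6, 5, 4, 3, 2, 1]
        for (i, j), v in zip([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], vals):
            w[i, j] = w[j, i] = v
        c = Connectome("s", w, list("abcd"))
        t = proportional_threshold(c, 0.5)
        np.testing.assert_array_equal(
            t.weights, oracles.threshold_sort_and_cut(w, 0.5)
        )
        assert density(t) == 0.5

    def test_target_one_is_identity(self, rng):
        c = random_connectome(rng, 10)
        np.testing.assert_array_equal(
            proportional_threshold(c, 1.0).weights, c.weights
        )

    def test_target_at_current_density_unchanged(self, rng):
        c = random_connectome(rng, 10, density=0.4)
        t = proportional_threshold(c, density(c))
        np.testing.assert_array_equal(t.weights, c.weights)

    def test_matches_sort_and_cut_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            c = random_connectome(rng, n, density=0.8)
            target = float(rng.uniform(0.1, 0.9))
            np.testing.assert_array_equal(
                proportional_threshold(c, target).weights,
                oracles.threshold_sort_and_cut(c.weights, target),
            )

    def test_deterministic_tie_break(self):
        w = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = 1.0  # all weights tie
        c = Connectome("s", w, list("abcd"))
        t1 = proportional_threshold(c, 0.5)
        t2 = proportional_threshold(c, 0.5)
        np.testing.assert_array_equal(t1.weights, t2.weights)
        # lexicographically first pairs survive
        assert t1.weights[0, 1] == 1 and t1.weights[0, 2] == 1 and t1.weights[0, 3] == 1


class TestCostCorrection:
    def test_default_grid_has_46_densities(self):
        grid = default_density_grid()
        assert len(grid) == 46
        assert grid[0] == 0.05 and grid[-1] == 0.50

    def test_already_sparse_network_constant_across_grid(self, rng):
        c = random_connectome(rng, 20, density=0.04)
        cc = cost_corrected_features(c, np.array([0.05, 0.10, 0.20]))
        assert np.ptp(cc.global_efficiency) == 0.0
        assert cc.cost_corrected["global_efficiency"] == pytest.approx(
            global_efficiency(c)
        )

    def test_cost_corrected_equals_independent_per_density_mean(self, rng):
        c = random_connectome(rng, 12, density=0.9)
        grid = np.array([0.2, 0.3, 0.4])
        cc = cost_corrected_features(c, grid)
        manual = np.mean(
            [global_efficiency(proportional_threshold(c, d)) for d in grid]
        )
        assert cc.cost_corrected["global_efficiency"] == pytest.approx(manual)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            cost_corrected_features(random_connectome(rng, 5), np.array([]))

    def test_local_efficiency_is_mean_of_nodal(self, rng):
        c = random_connectome(rng, 10, density=0.8)
        cc = cost_corrected_features(c, np.array([0.3]))
        assert cc.local_efficiency[0] == pytest.approx(
            nodal_efficiency(proportional_threshold(c, 0.3)).mean()
        )


class TestInvariants:
    def test_efficiency_monotone_in_density(self, rng):
        c = random_connectome(rng, 15, density=0.9)
        effs = [
            global_efficiency(proportional_threshold(c, d))
            for d in (0.1, 0.2, 0.3, 0.5, 0.8)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))

    def test_permutation_equivariance(self, rng):
        c = random_connectome(rng, 9, density=0.6)
        perm = rng.permutation(9)
        cp = Connectome(
            "p", c.weights[np.ix_(perm, perm)], [c.node_ids[i] for i in perm]
        )
        assert global_efficiency(cp) == pytest.approx(global_efficiency(c))
        np.testing.assert_allclose(
            nodal_strength(cp), nodal_strength(c)[perm]
        )
        np.testing.assert_allclose(
            nodal_efficiency(cp), nodal_efficiency(c)[perm], atol=1e-12
        )

    def test_weight_scaling_behaviour(self, rng):
        c = random_connectome(rng, 8, density=0.7)
        s = 3.7
        cs = Connectome("x", c.weights * s, list(c.node_ids))
        assert density(cs) == density(c)
        np.testing.assert_array_equal(nodal_degree(cs), nodal_degree(c))
        np.testing.assert_allclose(nodal_strength(cs), nodal_strength(c) * s)
        assert global_efficiency(cs) == pytest.approx(global_efficiency(c) * s)
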
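"""Graph metrics against brute-force and networkx oracles; sweep contracts."""

import numpy as np
import networkx as nx
import pytest

from dynconn.containers import WindowStack
from dynconn import graphs as gm


from graph_oracles import (
    brute_char_path,
    brute_clustering,
    brute_distances,
    brute_global_eff,
    brute_local_eff,
    random_adj,
)

# ------------------------------------------------------- raw metric suite
class TestMetricOracles:
    def test_fifty_random_graphs_match_brute_force_exactly(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            adj = random_adj(rng, n, rng.uniform(0.2, 0.8))
            per, mean_c = gm.clustering_coefficient(adj)
            bper, bmean = brute_clustering(adj)
            np.testing.assert_allclose(per, bper, atol=1e-12)
            assert mean_c == pytest.approx(bmean, abs=1e-12)
            l_obs = gm.char_path_length(adj)
            l_brute = brute_char_path(adj)
            if np.isnan(l_brute):
                assert np.isnan(l_obs)
            else:
                assert l_obs == pytest.approx(l_brute, abs=1e-12)
            assert gm.global_efficiency(adj) == pytest.approx(
                brute_global_eff(adj), abs=1e-12)
            assert gm.local_efficiency(adj) == pytest.approx(
                brute_local_eff(adj), abs=1e-12)

    def test_against_networkx_cross_check(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            adj = random_adj(rng, 9, 0.5)
            g = nx.from_numpy_array(adj.astype(int))
            _, mean_c = gm.clustering_coefficient(adj)
            assert mean_c == pytest.approx(nx.average_clustering(g), abs=1e-12)
            assert gm.global_efficiency(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12)

    def test_complete_graph_k5(self):
        adj = ~np.eye(5, dtype=bool)
        assert gm.clustering_coefficient(adj)[1] == 1.0
        assert gm.char_path_length(adj) == 1.0
        assert gm.global_efficiency(adj) == 1.0
        assert gm.local_efficiency(adj) == 1.0

    def test_star_graph(self):
        adj = np.zeros((6, 6), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        assert gm.clustering_coefficient(adj)[1] == 0.0
        assert gm.local_efficiency(adj) == 0.0

    def test_path_graph_p3(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        assert gm.char_path_length(adj) == pytest.approx(4 / 3)
        assert gm.global_efficiency(adj) == pytest.approx(5 / 6)

    def test_disjoint_k2_pairs_excluded(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        assert gm.char_path_length(adj) == 1.0
        assert gm.connected_pair_fraction(adj) == pytest.approx(4 / 12)

    def test_empty_graph_efficiency_zero(self):
        assert gm.global_efficiency(np.zeros((5, 5), dtype=bool)) == 0.0


class TestBinarize:
    def test_exact_edge_count_all_positive(self, rng):
        vals = np.abs(rng.standard_normal((5, 5))) + 0.1
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)
        g = gm.binarize_at_sparsity(vals, 0.4)
        assert g.n_edges == 4  # round(0.4 * 10)

    def test_all_negative_gives_empty_graph(self, rng):
        vals = -np.abs(rng.standard_normal((6, 6)))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)
        g = gm.binarize_at_sparsity(vals, 0.3)
        assert g.n_edges == 0
        assert g.achieved_sparsity == 0.0

    def test_tie_breaking_lexicographic(self):
        # brute-force ranking oracle on a 6-node toy with deliberate ties
        c = 6
        vals = np.zeros((c, c))
        iu, ju = np.triu_indices(c, k=1)
        weights = np.array([0.9, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
                            0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.3])
        vals[iu, ju] = weights
        vals = vals + vals.T
        g = gm.binarize_at_sparsity(vals, 3 / 15)  # keep 3 of 15
        # oracle: sort (weight desc, edge index asc) by explicit enumeration
        ranked = sorted(range(15), key=lambda e: (-weights[e], e))
        expected = set(ranked[:3])
        kept = {e for e in range(15) if g.adjacency[iu[e], ju[e]]}
        assert kept == expected

    def test_sparsity_bounds_validated(self):
        with pytest.raises(ValueError):
            gm.binarize_at_sparsity(np.eye(4), 0.0)


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        adj = random_adj(rng, 15, 0.3)
        ref = gm.random_reference(adj, seed=3)
        np.testing.assert_array_equal(
            np.sort(ref.degrees()), np.sort(adj.sum(axis=1))
        )

    def test_triangle_unchanged(self):
        adj = ~np.eye(3, dtype=bool)
        ref = gm.random_reference(adj, seed=1)
        np.testing.assert_array_equal(ref.adjacency, adj)

    def test_rewiring_destroys_ring_clustering(self):
        # ring lattice of 20 nodes, degree 4 has C = 0.5; rewiring lowers it
        n = 20
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for d in (1, 2):
                adj[i, (i + d) % n] = adj[(i + d) % n, i] = True
        _, c_ring = gm.clustering_coefficient(adj)
        cs = [gm.clustering_coefficient(gm.random_reference(adj, seed=s).adjacency)[1]
              for s in range(20)]
        assert np.mean(cs) < c_ring

    def test_deterministic_under_seed(self, rng):
        adj = random_adj(rng, 12, 0.4)
        a = gm.random_reference(adj, seed=9)
        b = gm.random_reference(adj, seed=9)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestSmallWorld:
    def test_sigma_is_gamma_over_lambda(self, rng):
        adj = random_adj(rng, 20, 0.3)
        sw = gm.small_world(adj, n_rand=10, seed=0)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam)

    def test_random_graph_near_unity(self, rng):
        # an ER-like graph is its own null: gamma and lambda ~ 1
        adj = random_adj(rng, 30, 0.25)
        sw = gm.small_world(adj, n_rand=20, seed=1)
        assert abs(sw.gamma - 1) < 0.5
        assert abs(sw.lam - 1) < 0.2

    def test_watts_strogatz_ring_is_small_world(self):
        g = nx.connected_watts_strogatz_graph(30, 6, 0.1, seed=4)
        adj = nx.to_numpy_array(g).astype(bool)
        sw = gm.small_world(adj, n_rand=20, seed=2)
        assert sw.sigma > 1

    def test_determinism(self, rng):
        adj = random_adj(rng, 15, 0.4)
        assert gm.small_world(adj, n_rand=5, seed=8) == gm.small_world(
            adj, n_rand=5, seed=8)


class TestCurvesAndAUC:
    def test_flat_curve_auc(self):
        grid = gm.default_sparsity_grid()
        assert grid.size == 41
        m = 2.5
        assert gm.auc_trapezoid(np.full(41, m), grid) == pytest.approx(0.40 * m)

    def test_eg_monotone_nondecreasing_in_sparsity(self, rng):
        for _ in range(3):
            vals = rng.standard_normal((20, 20))
            vals = 0.5 * (vals + vals.T)
            np.fill_diagonal(vals, 0.0)
            curves = gm.metric_curves(vals, n_rand=0)
            eg = curves["eg"].values
            assert np.all(np.diff(eg) >= -1e-12)

    def test_edge_count_monotone_along_grid(self, rng):
        vals = np.abs(rng.standard_normal((15, 15)))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)
        counts = [gm.binarize_at_sparsity(vals, s).n_edges
                  for s in gm.default_sparsity_grid()]
        assert np.all(np.diff(counts) >= 0)

    def test_curves_auc_consistent_with_trapezoid(self, rng):
        vals = rng.standard_normal((12, 12))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)
        curves = gm.metric_curves(vals, n_rand=2, seed=5)
        for m, curve in curves.items():
            assert curve.auc == pytest.approx(
                np.trapezoid(curve.values, curve.sparsity_grid), nan_ok=True)


class TestDynamicVariance:
    def _stack(self, windows):
        w = np.asarray(windows, dtype=float)
        return WindowStack(windows=w, window_length_tr=22, sigma_tr=3.0,
                           step_tr=1, onsets=np.arange(w.shape[0]),
                           subject_id="s")

    def test_identical_windows_zero_variance(self, rng):
        m = rng.standard_normal((10, 10))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        dv = gm.dynamic_metric_variance(self._stack([m] * 4), n_rand=2, seed=0)
        for name in ("eg", "eloc"):
            assert dv[name].variance_of_window_auc == pytest.approx(0.0, abs=1e-20)
            assert dv[name].per_window_auc.shape == (4,)

    def test_density_shift_raises_eg_variance(self, rng):
        # windows alternating dense/sparse positive structure vs constant
        dense = np.abs(rng.standard_normal((10, 10))) + 0.5
        sparse = dense.copy()
        sparse[np.abs(sparse) < 1.0] *= -1  # push many edges negative
        for m in (dense, sparse):
            np.fill_diagonal(m, 0.0)
        dense, sparse = 0.5 * (dense + dense.T), 0.5 * (sparse + sparse.T)
        switching = self._stack([dense, sparse, dense, sparse])
        stable = self._stack([dense] * 4)
        dv_switch = gm.dynamic_metric_variance(switching, n_rand=0)
        dv_stable = gm.dynamic_metric_variance(stable, n_rand=0)
        assert (dv_switch["eg"].variance_of_window_auc
                > dv_stable["eg"].variance_of_window_auc)

    def test_single_window_rejected(self, rng):
        m = rng.standard_normal((6, 6))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        with pytest.raises(ValueError):
            gm.dynamic_metric_variance(self._stack([m]), n_rand=0)
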
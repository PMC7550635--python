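import numpy as np
import pytest

from connectomeclf.graphmetrics import (
    betweenness,
    build_null_ensemble,
    identify_hubs,
    metric_auc,
    modularity_greedy,
    modularity_q,
    nodal_clustering,
    nodal_local_efficiency,
    rewire_degree_preserving,
    shortest_path_metrics,
    small_world_normalize,
)
from connectomeclf.network import SparsityGrid, threshold_series

from _oracles import (
    bf_betweenness,
    bf_clustering,
    bf_local_efficiency,
    bf_path_metrics,
    random_adjacency,
)


def complete_graph(n):
    a = np.ones((n, n), dtype=int)
    np.fill_diagonal(a, 0)
    return a


def star_graph(n):
    a = np.zeros((n, n), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return a


def path_graph(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


class TestClustering:
    def test_clique_and_star(self):
        assert nodal_clustering(complete_graph(4)).tolist() == [1.0] * 4
        assert nodal_clustering(star_graph(5)).tolist() == [0.0] * 5

    def test_matches_triangle_enumeration(self, rng):
        for _ in range(30):
            a = random_adjacency(12, rng.uniform(0.1, 0.7), rng)
            np.testing.assert_allclose(nodal_clustering(a), bf_clustering(a), atol=1e-12)


class TestShortestPaths:
    def test_complete_graph(self):
        m = shortest_path_metrics(complete_graph(5))
        assert m["Lp"] == 1.0
        assert m["Eglobal"] == 1.0
        assert np.allclose(m["nodal_efficiency"], 1.0)

    def test_path_graph_hand_enumeration(self):
        # distance multiset {1,1,1,2,2,3}
        m = shortest_path_metrics(path_graph(4))
        assert m["Lp"] == pytest.approx(10 / 6)
        assert m["Eglobal"] == pytest.approx(13 / 18)

    def test_disconnected_cliques(self):
        a = np.zeros((6, 6), dtype=int)
        a[np.ix_([0, 1, 2], [0, 1, 2])] = 1
        a[np.ix_([3, 4, 5], [3, 4, 5])] = 1
        np.fill_diagonal(a, 0)
        m = shortest_path_metrics(a)
        assert np.allclose(m["nodal_efficiency"], 2 / 5)  # 2 reachable of 5, 1/inf = 0

    def test_edgeless_graph_flagged(self):
        with pytest.warns(UserWarning, match="edgeless"):
            m = shortest_path_metrics(np.zeros((4, 4), dtype=int))
        assert np.isnan(m["Lp"])
        assert m["Eglobal"] == 0.0


class TestBetweenness:
    def test_path_and_cycle(self):
        assert betweenness(path_graph(3)).tolist() == [0.0, 1.0, 0.0]
        cycle = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]]
        )
        np.testing.assert_allclose(betweenness(cycle), 0.5)

    def test_matches_path_enumeration(self, rng):
        for _ in range(30):
            a = random_adjacency(10, rng.uniform(0.15, 0.6), rng)
            np.testing.assert_allclose(betweenness(a), bf_betweenness(a), atol=1e-9)


class TestLocalEfficiency:
    def test_clique_and_star(self):
        assert nodal_local_efficiency(complete_graph(4)).tolist() == [1.0] * 4
        assert nodal_local_efficiency(star_graph(5))[0] == 0.0

    def test_matches_induced_subgraph_oracle(self, rng):
        for _ in range(20):
            a = random_adjacency(10, rng.uniform(0.2, 0.7), rng)
            np.testing.assert_allclose(
                nodal_local_efficiency(a), bf_local_efficiency(a), atol=1e-12
            )


class TestModularity:
    def test_two_cliques_component_partition(self):
        a = np.zeros((8, 8), dtype=int)
        a[np.ix_(range(4), range(4))] = 1
        a[np.ix_(range(4, 8), range(4, 8))] = 1
        np.fill_diagonal(a, 0)
        assert modularity_q(a, [0, 0, 0, 0, 1, 1, 1, 1]) == pytest.approx(0.5)
        part = modularity_greedy(a)
        assert part.q == pytest.approx(0.5)
        assert part.n_modules == 2

    def test_single_module_is_zero(self, rng):
        a = random_adjacency(7, 0.5, rng)
        if a.sum() == 0:
            a[0, 1] = a[1, 0] = 1
        assert modularity_q(a, np.zeros(7, dtype=int)) == pytest.approx(0.0)

    def test_partition_bookkeeping_consistent(self, rng):
        a = random_adjacency(12, 0.3, rng)
        a[0, 1] = a[1, 0] = 1
        part = modularity_greedy(a)
        total = a.sum() // 2
        assert part.within_edges.sum() <= total
        assert part.degree_sums.sum() == 2 * total
        assert part.q == pytest.approx(modularity_q(a, part.assignment))

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity_greedy(np.zeros((5, 5), dtype=int))


class TestNullModel:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(10):
            a = random_adjacency(15, 0.3, rng)
            r = rewire_degree_preserving(a, rng)
            np.testing.assert_array_equal(a.sum(1), r.sum(1))
            assert np.array_equal(r, r.T)
            assert np.all(np.diag(r) == 0)

    def test_self_null_consistency(self, rng):
        # a rewired graph scored against its own null family: gamma, lambda ~ 1
        a = random_adjacency(20, 0.3, rng)
        ens = build_null_ensemble(a, n_random=30, seed=0)
        cp = float(nodal_clustering(a).mean())
        lp = shortest_path_metrics(a)["Lp"]
        gamma, lam, _ = small_world_normalize(cp, lp, ens)
        se_g = ens.cp_values.std(ddof=1) / ens.mean_cp / np.sqrt(30)
        se_l = np.nanstd(ens.lp_values, ddof=1) / ens.mean_lp / np.sqrt(30)
        assert abs(gamma - 1) < max(3 * se_g, 0.2)
        assert abs(lam - 1) < max(3 * se_l, 0.1)

    def test_lattice_with_shortcuts_is_small_world(self):
        # ring lattice (k=4) plus a few shortcuts: sigma > 1
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 30
            a = np.zeros((n, n), dtype=int)
            for i in range(n):
                for d in (1, 2):
                    a[i, (i + d) % n] = a[(i + d) % n, i] = 1
            for _ in range(5):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    a[i, j] = a[j, i] = 1
            ens = build_null_ensemble(a, n_random=20, seed=seed)
            cp = float(nodal_clustering(a).mean())
            lp = shortest_path_metrics(a)["Lp"]
            _, _, sigma = small_world_normalize(cp, lp, ens)
            hits += sigma > 1
        assert hits >= 9

    def test_ensemble_deterministic(self, rng):
        a = random_adjacency(15, 0.3, rng)
        e1 = build_null_ensemble(a, n_random=5, seed=42)
        e2 = build_null_ensemble(a, n_random=5, seed=42)
        assert e1.mean_cp == e2.mean_cp and e1.mean_lp == e2.mean_lp


class TestAggregation:
    def test_metric_auc_is_plain_sum(self):
        grid = SparsityGrid()
        assert metric_auc([0.3] * 49, grid) == pytest.approx(14.7)
        assert metric_auc([0.0] * 49, grid) == 0.0
        assert metric_auc(np.arange(1, 50), grid) == 1225
        with pytest.raises(ValueError, match="49"):
            metric_auc([1.0] * 48, grid)

    def test_hub_selection(self):
        assert identify_hubs(np.arange(90)).size == 5  # ceil(0.05 * 90)
        w = np.zeros(20)
        w[13] = 2.0
        assert identify_hubs(w).tolist() == [13]
        tied = np.ones(40)
        assert identify_hubs(tied).tolist() == [0, 1]  # index-ordered under ties

    def test_degree_sum_invariant_and_bounds(self, rng):
        for _ in range(50):
            a = random_adjacency(rng.integers(4, 14), rng.uniform(0.1, 0.9), rng)
            assert a.sum() == 2 * (a.sum() // 2)
            c = nodal_clustering(a)
            assert np.all((0 <= c) & (c <= 1))
            m = shortest_path_metrics(a)
            assert np.all((0 <= m["nodal_efficiency"]) & (m["nodal_efficiency"] <= 1))
            le = nodal_local_efficiency(a)
            assert np.all((0 <= le) & (le <= 1))
            assert 0 <= m["Eglobal"] <= 1

    def test_eglobal_monotone_under_densification(self, rng):
        w = np.abs(rng.standard_normal((15, 15)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        graphs = threshold_series(w, SparsityGrid(0.1, 0.9, 0.1))
        eg = [shortest_path_metrics(g)["Eglobal"] for g in graphs]
        assert np.all(np.diff(eg) >= -1e-12)

    def test_nodal_shortest_path_matches_oracle(self, rng):
        for _ in range(20):
            a = random_adjacency(10, rng.uniform(0.15, 0.6), rng)
            sp = shortest_path_metrics(a)
            nsp, neff, lp, eg = bf_path_metrics(a)
            np.testing.assert_allclose(sp["nodal_shortest_path"], nsp, atol=1e-12)
            np.testing.assert_allclose(sp["nodal_efficiency"], neff, atol=1e-12)
            if not np.isnan(lp):
                assert sp["Lp"] == pytest.approx(lp)
            assert sp["Eglobal"] == pytest.approx(eg)
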
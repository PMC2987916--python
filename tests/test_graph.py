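import networkx as nx
import numpy as np
import pytest

import covnet
from covnet import ContractError, DisconnectedNetworkError
from covnet.graph import edge_count_for_sparsity, top_k_adjacency
from covnet.network import CorrelationMatrix

from conftest import make_network
from oracles import (brute_betweenness, brute_cp, brute_lp, brute_distances,
                     random_connected_graph)


def _net_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return make_network(adj)


def _ring_lattice(n=90, k=6):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            adj[i, j] = adj[j, i] = True
    return make_network(adj)


class TestThresholding:
    def test_sparsity_one_gives_complete_graph(self, nc_cohort):
        corr = covnet.cohort_correlation(nc_cohort)
        net = covnet.threshold_by_sparsity(corr, 1.0)
        assert net.n_edges == 4005
        assert net.sparsity == 1.0

    def test_rounding_half_up(self):
        assert edge_count_for_sparsity(1.0, 4005) == 4005
        assert edge_count_for_sparsity(0.15, 4005) == 601  # 600.75
        assert edge_count_for_sparsity(0.5 / 4005, 4005) == 1  # exactly half rounds up
        assert edge_count_for_sparsity(0.4 / 4005, 4005) == 0

    def test_zero_edges_warns(self, small_atlas):
        corr = CorrelationMatrix(r=np.eye(10), n_subjects=10, atlas=small_atlas)
        with pytest.warns(UserWarning, match="zero edges"):
            net = covnet.threshold_by_sparsity(corr, 0.001)
        assert net.n_edges == 0

    def test_invalid_sparsity(self, small_atlas):
        corr = CorrelationMatrix(r=np.eye(10), n_subjects=10, atlas=small_atlas)
        for s in (0.0, -0.1, 1.2):
            with pytest.raises(ContractError):
                covnet.threshold_by_sparsity(corr, s)

    def test_top_k_matches_exhaustive_sort(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 5
            r = rng.uniform(-1, 1, (n, n))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            adj = top_k_adjacency(r, 3)
            iu, ju = np.triu_indices(n, k=1)
            order = sorted(range(len(iu)), key=lambda t: (-abs(r[iu[t], ju[t]]), iu[t], ju[t]))
            expected = {(iu[t], ju[t]) for t in order[:3]}
            got = {(i, j) for i, j in zip(*np.nonzero(np.triu(adj, 1)))}
            assert got == expected

    def test_positive_ranking_mode(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = -0.9
        r[2, 3] = r[3, 2] = 0.5
        assert top_k_adjacency(r, 1, rank="absolute")[0, 1]
        assert top_k_adjacency(r, 1, rank="positive")[2, 3]

    def test_edge_sets_nested_across_sparsities(self, nc_cohort):
        corr = covnet.cohort_correlation(nc_cohort)
        prev = None
        for s in (0.05, 0.10, 0.20, 0.40):
            edges = set(covnet.threshold_by_sparsity(corr, s).edges())
            if prev is not None:
                assert prev <= edges
            prev = edges


class TestClusteringAndPaths:
    def test_complete_graph(self):
        n = 4
        net = _net_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
        assert covnet.clustering_coefficients(net).tolist() == [1.0] * 4
        assert covnet.average_clustering(net) == 1.0
        assert covnet.mean_path_length(net) == 1.0

    def test_star_graph_clustering_zero(self):
        net = _net_from_edges(6, [(0, i) for i in range(1, 6)])
        assert covnet.average_clustering(net) == 0.0

    def test_triangle_with_pendant(self):
        net = _net_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        c = covnet.clustering_coefficients(net)
        assert c[0] == pytest.approx(1 / 3)
        assert c[1] == c[2] == 1.0 and c[3] == 0.0

    def test_path_graph_lengths(self):
        net = _net_from_edges(3, [(0, 1), (1, 2)])
        d = covnet.distance_matrix(net)
        per_node = d.sum(axis=1) / 2
        assert per_node.tolist() == [1.5, 1.0, 1.5]
        assert covnet.mean_path_length(net) == pytest.approx(4 / 3)

    def test_disconnected_raises_with_components(self):
        net = _net_from_edges(5, [(0, 1), (2, 3), (3, 4)])
        with pytest.raises(DisconnectedNetworkError) as err:
            covnet.mean_path_length(net)
        assert sorted(err.value.component_sizes, reverse=True) == [3, 2]


class TestBetweennessAndHubs:
    def test_star_center_is_sole_hub(self):
        net = _net_from_edges(6, [(0, i) for i in range(1, 6)])
        m = covnet.nodal_metrics(net)
        assert m.loc[0, "betweenness"] == 10.0  # C(5,2) pairs through center
        assert m.loc[0, "normalized_betweenness"] == pytest.approx(6.0)
        assert covnet.detect_hubs(m) == [1]  # region id of the center

    def test_cycle_has_no_hubs(self):
        net = _net_from_edges(8, [(i, (i + 1) % 8) for i in range(8)])
        m = covnet.nodal_metrics(net)
        np.testing.assert_allclose(m["normalized_betweenness"], 1.0)
        assert covnet.detect_hubs(m) == []

    def test_complete_graph_zero_betweenness_handled(self):
        net = _net_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        m = covnet.nodal_metrics(net)
        np.testing.assert_array_equal(m["normalized_betweenness"], 0.0)
        assert covnet.detect_hubs(m) == []

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            adj = random_connected_graph(rng, n_max=12)
            net = make_network(adj)
            mine = covnet.nodal_metrics(net)["betweenness"].to_numpy()
            g = net.to_networkx()
            ref = nx.betweenness_centrality(g, normalized=False)
            np.testing.assert_allclose(mine, [ref[i] for i in range(len(adj))], atol=1e-12)


class TestRewiring:
    def test_degree_sequence_preserved(self, tiny_net):
        out = covnet.rewire_preserving_degrees(tiny_net, n_swaps=2000, seed=1)
        np.testing.assert_array_equal(np.sort(out.degrees()), np.sort(tiny_net.degrees()))
        assert out.is_connected()

    def test_triangle_is_rigid(self):
        net = _net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.warns(UserWarning, match="retry budget"):
            out = covnet.rewire_preserving_degrees(net, n_swaps=5, seed=0, max_tries=500)
        np.testing.assert_array_equal(out.adjacency, net.adjacency)
        assert out.n_swaps_accepted == 0

    def test_rewiring_destroys_lattice_clustering(self):
        net = _ring_lattice()
        cp0 = covnet.average_clustering(net)
        below = 0
        n_seeds = 100
        for seed in range(n_seeds):
            out = covnet.rewire_preserving_degrees(net, n_swaps=10 * net.n_edges, seed=seed)
            below += covnet.average_clustering(out) < cp0
        assert below >= 95

    def test_deterministic_under_seed(self, tiny_net):
        a = covnet.rewire_preserving_degrees(tiny_net, n_swaps=500, seed=42)
        b = covnet.rewire_preserving_degrees(tiny_net, n_swaps=500, seed=42)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestSmallWorldIndices:
    def test_identity_surrogate(self, tiny_net):
        gm = covnet.small_world_indices(tiny_net, n_random=1, seed=0, swaps_per_edge=0)
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lam == pytest.approx(1.0)

    def test_ring_lattice_is_small_world_after_light_rewiring(self):
        # Watts-Strogatz-style: high clustering, near-random path length
        lattice = _ring_lattice(90, 14)  # K = 630
        lightly = covnet.rewire_preserving_degrees(lattice, n_swaps=60, seed=3)
        gm = covnet.small_world_indices(lightly, n_random=10, seed=4)
        assert gm.gamma > 1.0
        assert 0.9 <= gm.lam <= 1.3

    def test_bitwise_reproducible(self, tiny_net):
        g1 = covnet.small_world_indices(tiny_net, n_random=3, seed=7)
        g2 = covnet.small_world_indices(tiny_net, n_random=3, seed=7)
        assert g1 == g2


class TestOracleEquivalence:
    def test_metrics_match_bruteforce_on_small_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            adj = random_connected_graph(rng)
            net = make_network(adj)
            assert covnet.average_clustering(net) == pytest.approx(float(brute_cp(adj)), abs=1e-12)
            assert covnet.mean_path_length(net) == pytest.approx(float(brute_lp(adj)), abs=1e-12)
            d = covnet.distance_matrix(net)
            for (s, t), dist in brute_distances(adj).items():
                assert d[s, t] == dist
            b = covnet.nodal_metrics(net)["betweenness"].to_numpy()
            np.testing.assert_allclose(b, [float(x) for x in brute_betweenness(adj)], atol=1e-9)
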
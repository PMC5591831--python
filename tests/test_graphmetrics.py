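"""Clustering, path length, degree-preserving nulls, normalized metrics."""

import numpy as np
import networkx as nx
import pytest

from mmgraph.connectivity import ConnectivityMatrix
from mmgraph.graphmetrics import (
    characteristic_path_length,
    clustering_coefficient,
    metrics_over_sparsity,
    node_gamma_summary,
    normalized_metrics,
    random_reference,
)
from mmgraph.synthdata import generate_small_world_graph
from tests.conftest import random_adjacency, random_symmetric_matrix


def _adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        node_c, C = clustering_coefficient(_adj_from_edges(3, [(0, 1), (1, 2), (0, 2)]))
        assert np.allclose(node_c, 1.0) and C == 1.0

    def test_star_has_no_triangles(self):
        node_c, C = clustering_coefficient(
            _adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        )
        assert C == 0.0

    def test_square_with_one_diagonal(self):
        # edges 12,23,34,41,13 -> per-node 2/3, 1, 2/3, 1 -> C = 5/6
        adj = _adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        node_c, C = clustering_coefficient(adj)
        assert np.allclose(sorted(node_c), [2 / 3, 2 / 3, 1.0, 1.0])
        assert C == pytest.approx(5 / 6)

    def test_degree_below_two_gets_zero(self):
        node_c, _ = clustering_coefficient(_adj_from_edges(3, [(0, 1)]))
        assert np.allclose(node_c, 0.0)


class TestPathLength:
    def test_complete_graph(self):
        L, frag = characteristic_path_length(np.uint8(1) - np.eye(4, dtype=np.uint8))
        assert L == 1.0 and not frag

    def test_path_of_three(self):
        L, frag = characteristic_path_length(_adj_from_edges(3, [(0, 1), (1, 2)]))
        assert L == pytest.approx(4 / 3)

    def test_five_cycle(self):
        edges = [(i, (i + 1) % 5) for i in range(5)]
        L, _ = characteristic_path_length(_adj_from_edges(5, edges))
        assert L == pytest.approx(1.5)

    def test_fragmented_graph_averages_reachable_pairs(self):
        # two disjoint edges: all reachable distances are 1
        L, frag = characteristic_path_length(_adj_from_edges(4, [(0, 1), (2, 3)]))
        assert L == 1.0 and frag

    def test_edgeless_graph_fails(self):
        with pytest.raises(ValueError, match="no edges"):
            characteristic_path_length(np.zeros((3, 3), dtype=np.uint8))

    def test_efficiency_mode(self):
        L, frag = characteristic_path_length(
            _adj_from_edges(3, [(0, 1), (1, 2)]), mode="efficiency"
        )
        # harmonic mean of distances {1,1,2}: 1/((1+1+0.5)/3)
        assert L == pytest.approx(3 / 2.5)


class TestBruteForceEquivalence:
    def test_metrics_match_exhaustive_oracles_on_small_graphs(self, rng):
        # triad enumeration for clustering; Floyd-Warshall for distances
        for _ in range(100):
            n = int(rng.integers(3, 9))
            adj = random_adjacency(n, rng.uniform(0.2, 0.9), rng)
            if adj.sum() == 0:
                continue
            node_c, C = clustering_coefficient(adj)
            for i in range(n):
                nbrs = np.flatnonzero(adj[i])
                k = len(nbrs)
                tri = sum(
                    adj[a, b]
                    for ai, a in enumerate(nbrs)
                    for b in nbrs[ai + 1:]
                )
                expect = 0.0 if k < 2 else 2 * tri / (k * (k - 1))
                assert node_c[i] == pytest.approx(expect, abs=1e-14)
            # Floyd-Warshall
            dist = np.where(adj, 1.0, np.inf)
            np.fill_diagonal(dist, 0.0)
            for m in range(n):
                dist = np.minimum(dist, dist[:, [m]] + dist[[m], :])
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(dist[off])
            L, frag = characteristic_path_length(adj)
            assert frag == (~finite).any()
            assert L == pytest.approx(dist[off][finite].mean())

    def test_agrees_with_networkx_on_connected_graphs(self, rng):
        for seed in range(20):
            g = nx.gnp_random_graph(10, 0.5, seed=seed)
            if not nx.is_connected(g) or g.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(g, dtype=np.uint8)
            _, C = clustering_coefficient(adj)
            assert C == pytest.approx(nx.average_clustering(g))
            L, _ = characteristic_path_length(adj)
            assert L == pytest.approx(nx.average_shortest_path_length(g))


class TestRandomReference:
    def test_triangle_returned_unchanged_and_flagged(self):
        adj = _adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        out, n_swaps = random_reference(adj, seed=0)
        assert np.array_equal(out.adjacency, adj)
        assert n_swaps == 0

    def test_degree_sequence_preserved(self, rng):
        for seed in range(20):
            adj = random_adjacency(15, 0.3, rng)
            if adj.sum() < 4:
                continue
            out, _ = random_reference(adj, seed=seed)
            assert np.array_equal(
                np.sort(out.adjacency.sum(1)), np.sort(adj.sum(1))
            )
            assert np.all(np.diag(out.adjacency) == 0)

    def test_rewiring_destroys_lattice_clustering(self):
        # WS(100, 6, 0.05): clustering should drop below half on average
        ratios = []
        base = generate_small_world_graph(100, 6, 0.05, seed=1).adjacency
        _, C0 = clustering_coefficient(base)
        for seed in range(50):
            out, _ = random_reference(base, swaps_per_edge=10, seed=seed)
            _, C = clustering_coefficient(out)
            ratios.append(C / C0)
        assert np.mean(ratios) < 0.5

    def test_deterministic_for_fixed_seed(self, rng):
        adj = random_adjacency(20, 0.3, rng)
        a, _ = random_reference(adj, seed=99)
        b, _ = random_reference(adj, seed=99)
        assert np.array_equal(a.adjacency, b.adjacency)


class TestNormalizedMetrics:
    def test_er_graph_self_normalizes(self, rng):
        adj = random_adjacency(100, 0.3, rng)
        m = normalized_metrics(adj, n_null=50, seed=5)
        assert 0.9 <= m.gamma <= 1.1
        assert 0.95 <= m.lam <= 1.05

    def test_small_world_regime(self):
        adj = generate_small_world_graph(100, 6, 0.05, seed=2).adjacency
        m = normalized_metrics(adj, n_null=50, seed=3)
        assert m.sigma > 1.5

    def test_sigma_is_gamma_over_lambda(self, rng):
        adj = random_adjacency(30, 0.3, rng)
        m = normalized_metrics(adj, n_null=10, seed=1)
        assert m.sigma == m.gamma / m.lam

    def test_degenerate_null_fails(self):
        # a star admits no triangles in any degree-preserving reference
        star = _adj_from_edges(5, [(0, i) for i in range(1, 5)])
        with pytest.raises(ValueError, match="zero mean clustering"):
            normalized_metrics(star, n_null=5, seed=0)


class TestMetricsOverSparsity:
    def _cm(self, values):
        return ConnectivityMatrix(values=values)

    def test_default_grid_curve_length(self, rng):
        curve = metrics_over_sparsity(
            self._cm(random_symmetric_matrix(20, rng)), n_null=3, seed=0
        )
        assert len(curve.metrics) == 35
        assert len(curve.sparsity) == 35

    def test_node_permutation_leaves_curve_invariant(self, rng):
        vals = random_symmetric_matrix(15, rng)
        perm = rng.permutation(15)
        curve1 = metrics_over_sparsity(self._cm(vals), n_null=5, seed=2)
        curve2 = metrics_over_sparsity(
            self._cm(vals[np.ix_(perm, perm)]), n_null=5, seed=2
        )
        # graph-level metrics are isomorphism-invariant; nulls share seeds
        assert np.allclose(curve1.values("C"), curve2.values("C"))
        assert np.allclose(curve1.values("L"), curve2.values("L"))

    def test_planted_small_world_dominates_er_in_sigma(self, rng):
        from mmgraph.synthdata import covariance_from_graph

        ws = generate_small_world_graph(40, 8, 0.05, seed=1)
        cov = covariance_from_graph(ws, 0.2)
        noise = random_symmetric_matrix(40, rng) * 0.01
        sw_vals = np.clip(cov - np.diag(np.diag(cov)) + noise, -1, 1)
        er_vals = random_symmetric_matrix(40, rng) * 0.2
        grid = np.round(np.arange(15, 36) / 100, 2)
        c_sw = metrics_over_sparsity(self._cm(sw_vals), grid, n_null=10, seed=3)
        c_er = metrics_over_sparsity(self._cm(er_vals), grid, n_null=10, seed=4)
        assert (c_sw.values("sigma") > c_er.values("sigma")).all()


class TestNodeGammaSummary:
    def test_complete_graph_nodes_normalize_to_one(self):
        # K5 has a unique degree-preserving configuration: nulls == graph
        vals = 0.5 * (1 - np.eye(5))
        cm = ConnectivityMatrix(values=vals)
        curve = metrics_over_sparsity(cm, np.array([1.0]), n_null=3, seed=0)
        gamma, undefined = node_gamma_summary(curve)
        assert np.allclose(gamma, 1.0)
        assert not undefined.any()

    def test_output_length_matches_node_count(self, rng):
        cm = ConnectivityMatrix(values=random_symmetric_matrix(12, rng))
        curve = metrics_over_sparsity(cm, np.array([0.3, 0.4]), n_null=3, seed=1)
        gamma, undefined = node_gamma_summary(curve)
        assert gamma.shape == (12,) and undefined.shape == (12,)

    def test_triangle_rich_hub_exceeds_one(self, rng):
        # planted clique inside a sparse ring: clique nodes well above 1
        n = 20
        adj = _adj_from_edges(n, [(i, (i + 1) % n) for i in range(n)])
        for i in range(5):
            for j in range(i + 1, 5):
                adj[i, j] = adj[j, i] = 1
        vals = adj * 0.5 + random_symmetric_matrix(n, rng) * 0.01
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        cm = ConnectivityMatrix(values=np.clip(vals, -1, 1))
        curve = metrics_over_sparsity(cm, np.array([0.2]), n_null=20, seed=2)
        gamma, _ = node_gamma_summary(curve)
        assert np.nanmean(gamma[:5]) > 1.0
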
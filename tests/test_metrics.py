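"""Graph metrics: hand-computed fixtures, relabeling invariance,
networkx agreement, rewiring properties and small-world normalization."""

import numpy as np
import networkx as nx
import pytest

from subcovnet import metrics
from conftest import random_adjacency


def graph(edges, n):
    adj = np.zeros((n, n), dtype=int)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return adj


TRIANGLE_PENDANT = graph([(0, 1), (0, 2), (1, 2), (2, 3)], 4)
STAR5 = graph([(0, i) for i in range(1, 5)], 5)
PATH4 = graph([(0, 1), (1, 2), (2, 3)], 4)
K4 = graph([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)


class TestHandExamples:
    def test_clustering(self):
        assert metrics.clustering_coefficient(K4) == pytest.approx(1.0)
        assert metrics.clustering_coefficient(STAR5) == pytest.approx(0.0)
        # (1/3 + 1 + 1 + 0) / 4 for the triangle with one pendant
        assert metrics.clustering_coefficient(TRIANGLE_PENDANT) == pytest.approx(
            (1 / 3 + 1 + 1 + 0) / 4
        )

    def test_path_length(self):
        assert metrics.characteristic_path_length(K4)[0] == pytest.approx(1.0)
        lp, unreach = metrics.characteristic_path_length(PATH4)
        assert lp == pytest.approx(np.mean([1, 2, 3, 1, 2, 1]))
        assert unreach == 0
        # two disjoint edges: finite pairs only, 4 unreachable pairs
        lp, unreach = metrics.characteristic_path_length(graph([(0, 1), (2, 3)], 4))
        assert lp == pytest.approx(1.0)
        assert unreach == 4

    def test_empty_graph_has_no_path_length(self):
        with pytest.raises(ValueError, match="no connected pair"):
            metrics.characteristic_path_length(np.zeros((4, 4), dtype=int))

    def test_largest_component_convention(self):
        adj = graph([(0, 1), (1, 2), (3, 4)], 5)
        lp, _ = metrics.characteristic_path_length(adj, "largest_component")
        assert lp == pytest.approx(np.mean([1, 2, 1]))

    def test_global_efficiency(self):
        assert metrics.global_efficiency(K4) == pytest.approx(1.0)
        assert metrics.global_efficiency(np.zeros((4, 4), dtype=int)) == 0.0
        path3 = graph([(0, 1), (1, 2)], 3)
        assert metrics.global_efficiency(path3) == pytest.approx(np.mean([1, 1, 0.5]))

    def test_local_efficiency(self):
        assert metrics.local_efficiency(K4) == pytest.approx(1.0)
        assert metrics.local_efficiency(STAR5) == pytest.approx(0.0)
        assert metrics.local_efficiency(TRIANGLE_PENDANT) == pytest.approx(
            (1 / 3 + 1 + 1 + 0) / 4
        )

    def test_nodal_efficiency(self):
        assert metrics.nodal_efficiency(STAR5)[0] == pytest.approx(1.0)
        iso = graph([(0, 1)], 3)
        assert metrics.nodal_efficiency(iso)[2] == 0.0
        path3 = graph([(0, 1), (1, 2)], 3)
        assert metrics.nodal_efficiency(path3)[0] == pytest.approx((1 + 0.5) / 2)

    def test_betweenness(self):
        path3 = graph([(0, 1), (1, 2)], 3)
        assert metrics.betweenness(path3)[1] == pytest.approx(1.0)
        assert np.allclose(metrics.betweenness(K4), 0.0)
        assert metrics.betweenness(STAR5)[0] == pytest.approx(1.0)

    def test_degree(self):
        assert np.array_equal(metrics.degree(TRIANGLE_PENDANT), [2, 2, 3, 1])
        k17 = graph([(i, j) for i in range(17) for j in range(i + 1, 17)], 17)
        assert np.array_equal(metrics.degree(k17), [16] * 17)
        assert np.array_equal(metrics.degree(np.zeros((5, 5), int)), [0] * 5)


def test_relabeling_invariance(rng):
    """All metrics are invariant under random node permutations."""
    for _ in range(50):
        n = int(rng.integers(4, 12))
        adj = random_adjacency(rng, n)
        perm = rng.permutation(n)
        padj = adj[np.ix_(perm, perm)]
        assert metrics.clustering_coefficient(adj) == pytest.approx(
            metrics.clustering_coefficient(padj)
        )
        assert metrics.global_efficiency(adj) == pytest.approx(
            metrics.global_efficiency(padj)
        )
        assert metrics.local_efficiency(adj) == pytest.approx(
            metrics.local_efficiency(padj)
        )
        np.testing.assert_allclose(
            metrics.nodal_efficiency(adj)[perm], metrics.nodal_efficiency(padj)
        )
        np.testing.assert_allclose(
            metrics.betweenness(adj)[perm], metrics.betweenness(padj), atol=1e-12
        )
        if adj.sum():
            assert metrics.characteristic_path_length(adj)[0] == pytest.approx(
                metrics.characteristic_path_length(padj)[0]
            )


def test_agreement_with_networkx(rng):
    for _ in range(60):
        n = int(rng.integers(4, 17))
        adj = random_adjacency(rng, n)
        G = nx.from_numpy_array(adj)
        assert metrics.clustering_coefficient(adj) == pytest.approx(
            nx.average_clustering(G)
        )
        assert metrics.global_efficiency(adj) == pytest.approx(nx.global_efficiency(G))
        assert metrics.local_efficiency(adj) == pytest.approx(nx.local_efficiency(G))
        bc = nx.betweenness_centrality(G)
        np.testing.assert_allclose(
            metrics.betweenness(adj), [bc[i] for i in range(n)], atol=1e-12
        )


def test_global_efficiency_monotone_under_edge_addition(rng):
    for _ in range(20):
        n = int(rng.integers(5, 12))
        adj = random_adjacency(rng, n)
        zeros = np.argwhere(np.triu(adj == 0, 1))
        if not len(zeros):
            continue
        i, j = zeros[rng.integers(len(zeros))]
        denser = adj.copy()
        denser[i, j] = denser[j, i] = 1
        assert metrics.global_efficiency(denser) >= metrics.global_efficiency(adj) - 1e-12


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        for seed in range(10):
            adj = random_adjacency(rng, 17, 40)
            out, got = metrics.rewire_preserving_degree(adj, seed=seed)
            assert np.array_equal(out.sum(1), adj.sum(1))
            assert np.all(np.diag(out) == 0)
            assert np.array_equal(out, out.T)

    def test_complete_graph_unchanged(self):
        k6 = graph([(i, j) for i in range(6) for j in range(i + 1, 6)], 6)
        with pytest.warns(UserWarning, match="swaps"):
            out, got = metrics.rewire_preserving_degree(k6, seed=0)
        assert got == 0
        assert np.array_equal(out, k6)

    def test_rewired_ensemble_loses_clustering(self):
        """A clustered modular seed graph has higher Cp than its
        degree-preserving randomizations on average."""
        blocks = [list(range(0, 6)), list(range(6, 12)), list(range(12, 17))]
        edges = [(a, b) for blk in blocks for a in blk for b in blk if a < b]
        adj = graph(edges, 17)
        cp0 = metrics.clustering_coefficient(adj)
        cps = [
            metrics.clustering_coefficient(metrics.rewire_preserving_degree(adj, seed=s)[0])
            for s in range(100)
        ]
        assert all(
            out_sum == adj.sum() for out_sum in
            [metrics.rewire_preserving_degree(adj, seed=s)[0].sum() for s in range(5)]
        )
        assert np.mean(cps) < cp0


class TestNormalized:
    def test_self_ensemble_gives_unity(self, rng):
        adj = random_adjacency(rng, 12, 24)
        gamma, lam, sigma = metrics.normalized_metrics(
            adj, n_random=1, swap_multiplier=0, seed=0
        )
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_sigma_is_gamma_over_lambda(self, rng):
        adj = random_adjacency(rng, 14, 30)
        gamma, lam, sigma = metrics.normalized_metrics(adj, n_random=20, seed=3)
        assert sigma == pytest.approx(gamma / lam)

    def test_ring_lattice_is_small_world(self):
        adj = nx.to_numpy_array(nx.watts_strogatz_graph(17, 4, 0.05, seed=2)).astype(int)
        gamma, lam, sigma = metrics.normalized_metrics(adj, n_random=100, seed=7)
        assert gamma > 1.0
        assert sigma > 1.0
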
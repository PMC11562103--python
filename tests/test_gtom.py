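"""Correlation networks, GTOM overlap, and network scores."""

import networkx as nx
import numpy as np
import pytest

from gtomnet import (
    AdjacencyMatrix,
    ExpressionMatrix,
    adjacency_from_correlation,
    correlation_matrix,
    gtom,
    gtom_diff,
    gtom_score,
    reachable_sets,
    total_score,
)
from gtomnet.gtom import CorrelationMatrix

from conftest import random_adjacency


def brute_force_gtom(adj: np.ndarray, k: int) -> np.ndarray:
    """Independent oracle: BFS neighborhoods + literal overlap formula."""
    g = nx.from_numpy_array(adj)
    n = adj.shape[0]
    sets = []
    for i in range(n):
        dist = nx.single_source_shortest_path_length(g, i, cutoff=k + 1)
        sets.append({j for j, d in dist.items() if j != i})
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a_ij = adj[i, j]
            num = len(sets[i] & sets[j]) + a_ij
            den = min(len(sets[i]), len(sets[j])) + 1 - a_ij
            t[i, j] = num / den
    return t


class TestCorrelationMatrix:
    def test_hand_computed_pearson(self, tiny_expression):
        c = correlation_matrix(tiny_expression, method="pearson", axis="genes")
        assert c.values[0, 1] == pytest.approx(-1.0)
        assert c.values[0, 2] == pytest.approx(0.8)
        np.testing.assert_allclose(np.diag(c.values), 1.0)

    def test_proportional_rows_are_perfectly_correlated(self):
        x = ExpressionMatrix(
            np.array([[1.0, 2, 3], [2.0, 4, 6]]), ["a", "b"], ["s1", "s2", "s3"]
        )
        c = correlation_matrix(x)
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_spearman_is_invariant_under_monotone_transform(self):
        base = np.array([0.1, 0.9, 0.3, 0.7, 0.5])
        x = ExpressionMatrix(
            np.vstack([base, np.exp(base)]), ["a", "b"], [f"s{i}" for i in range(5)]
        )
        sp = correlation_matrix(x, method="spearman")
        pe = correlation_matrix(x, method="pearson")
        assert sp.values[0, 1] == pytest.approx(1.0)
        assert pe.values[0, 1] < 1.0

    def test_constant_rows_get_zero_correlation(self):
        x = ExpressionMatrix(
            np.array([[1.0, 1, 1], [1.0, 2, 3]]), ["a", "b"], ["s1", "s2", "s3"]
        )
        c = correlation_matrix(x)
        assert c.values[0, 1] == 0.0

    def test_too_few_entities_rejected(self):
        x = ExpressionMatrix(np.ones((1, 4)), ["a"], list("wxyz"))
        with pytest.raises(ValueError):
            correlation_matrix(x)


class TestAdjacency:
    def test_threshold_is_signed_and_boundary_inclusive(self):
        c = CorrelationMatrix(
            values=np.array([[1.0, 0.7, -0.9], [0.7, 1.0, 0.2], [-0.9, 0.2, 1.0]]),
            method="pearson",
            entity_ids=["a", "b", "c"],
        )
        a = adjacency_from_correlation(c, 0.7)
        assert a.values[0, 1] == 1  # exactly at the cutoff: connected
        assert a.values[0, 2] == 0  # strong anti-correlation: not connected
        assert np.all(np.diag(a.values) == 0)

    @pytest.mark.parametrize("cutoff", [0.0, 1.0, -0.2])
    def test_cutoff_range_enforced(self, cutoff):
        c = CorrelationMatrix(np.eye(2), "pearson", ["a", "b"])
        with pytest.raises(ValueError):
            adjacency_from_correlation(c, cutoff)


class TestReachableSets:
    def test_path_graph_neighborhoods(self, path_graph):
        n1 = reachable_sets(path_graph, 1)
        assert n1 == [{1}, {0, 2}, {1}]
        n2 = reachable_sets(path_graph, 2)
        assert n2[0] == {1, 2}

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = random_adjacency(rng, 50, 0.08)
            g = nx.from_numpy_array(a.values)
            for path_len in (1, 2, 3):
                got = reachable_sets(a, path_len)
                for i in range(50):
                    dist = nx.single_source_shortest_path_length(g, i, cutoff=path_len)
                    assert got[i] == {j for j, d in dist.items() if j != i}


class TestGtom:
    def test_path_graph_order_zero(self, path_graph):
        t = gtom(path_graph, 0).values
        assert t[0, 1] == pytest.approx(1.0)
        assert t[0, 2] == pytest.approx(0.5)
        assert t[1, 2] == pytest.approx(1.0)

    def test_path_graph_order_one(self, path_graph):
        t = gtom(path_graph, 1).values
        assert t[0, 1] == pytest.approx(1.0)
        assert t[0, 2] == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("k", [0, 1, 3])
    def test_complete_graph_saturates(self, k):
        m = 6
        a = AdjacencyMatrix(
            values=(np.ones((m, m)) - np.eye(m)).astype(int),
            cutoff=0.5,
            entity_ids=[f"n{i}" for i in range(m)],
        )
        t = gtom(a, k).values
        np.testing.assert_allclose(t, 1.0)

    def test_isolated_pair_scores_zero(self):
        a = AdjacencyMatrix(np.zeros((3, 3), dtype=int), 0.5, ["a", "b", "c"])
        t = gtom(a, 2).values
        assert t[0, 1] == 0.0
        assert t[0, 0] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            a = random_adjacency(rng, n, float(rng.uniform(0.1, 0.5)))
            for k in (0, 1, 2, 3):
                got = gtom(a, k).values
                want = brute_force_gtom(a.values, k)
                np.testing.assert_array_equal(got, want)

    def test_entries_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = random_adjacency(rng, 30, float(rng.uniform(0.05, 0.6)))
            t = gtom(a, int(rng.integers(0, 4))).values
            assert np.all(t >= 0.0) and np.all(t <= 1.0)


class TestGroupScores:
    def test_gtom_score_on_path_graph(self, path_graph):
        t = gtom(path_graph, 0)
        assert gtom_score(t, [0, 1], [0, 1]) == pytest.approx(1.0)
        assert gtom_score(t, [0], [2]) == pytest.approx(0.5)

    def test_constant_matrix_scores_the_constant(self):
        vals = np.full((4, 4), 0.3)
        np.fill_diagonal(vals, 1.0)
        from gtomnet.gtom import GtomMatrix

        t = GtomMatrix(vals, 0, list("abcd"))
        assert gtom_score(t, [0, 1], [2, 3]) == pytest.approx(0.3)
        assert gtom_score(t, [0, 1, 2], [0, 1, 2]) == pytest.approx(0.3)

    def test_same_singleton_pair_rejected(self, path_graph):
        t = gtom(path_graph, 0)
        with pytest.raises(ValueError):
            gtom_score(t, [1], [1])

    def test_gtom_diff_hand_value(self, path_graph):
        t = gtom(path_graph, 0)
        assert gtom_diff(t, [0, 1], [2]) == pytest.approx(0.25)

    def test_gtom_diff_extremes(self):
        # A internally complete and disconnected from B -> 1; A == B -> 0
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        adj = AdjacencyMatrix(a, 0.5, list("abcd"))
        t = gtom(adj, 0)
        assert gtom_diff(t, [0, 1], [2, 3]) == pytest.approx(1.0)
        assert gtom_diff(t, [0, 1], [0, 1]) == pytest.approx(0.0)


class TestTotalScore:
    def test_two_distinct_cores(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert total_score(g, [0.5, 0.5]) == pytest.approx(0.25)

    def test_core_plus_attached_satellite(self):
        g = np.array([[0.9, 0.6], [0.6, 0.2]])
        assert total_score(g, [0.5, 0.5]) == pytest.approx(0.126)

    def test_all_zero_scores(self):
        assert total_score(np.zeros((3, 3)), [0.4, 0.3, 0.3]) == pytest.approx(0.0)

    def test_ratio_sum_enforced(self):
        with pytest.raises(ValueError):
            total_score(np.eye(2) * 0.5, [0.5, 0.6])

    def test_matches_literal_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            m = int(rng.integers(2, 7))
            g = rng.random((m, m))
            g = (g + g.T) / 2
            r = rng.random(m)
            r = r / r.sum()
            want = 0.0
            for i in range(m):
                for j in range(i + 1, m):
                    want += r[i] * r[j] * (
                        g[i, i] * g[j, j] * (1 - g[i, j])
                        + g[i, i] * (1 - g[j, j]) * g[i, j]
                    )
            want /= m * (m - 1) / 2
            assert total_score(g, r) == pytest.approx(want, abs=1e-12)
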
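from collections import deque

import numpy as np
import pytest

from connethresh.core import BinaryEdgeSet, edge_set
from connethresh.metrics import (INVERSE_MEAN,
                                 betweenness_centrality, degree,
                                 global_efficiency, mean_strength,
                                 node_strength, subject_metric,
                                 subject_summary)
from connethresh.threshold import apply_absolute, apply_fixed_density

from conftest import from_edges, random_connected_connectome


# ---------------------------------------------------------------------------
# exhaustive-path oracles
# ---------------------------------------------------------------------------


def bfs_distances(adj, src):
    n = adj.shape[0]
    dist = {src: 0}
    q = deque([src])
    while q:
        v = q.popleft()
        for u in np.nonzero(adj[v])[0]:
            if u not in dist:
                dist[int(u)] = dist[v] + 1
                q.append(int(u))
    return dist


def all_shortest_paths(adj, s, t):
    """Every shortest s-t path, by BFS layers + backtracking."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in np.nonzero(adj[v])[0]:
            u = int(u)
            if u in dist and dist[u] == dist[v] - 1:
                back(u, [v] + acc)

    back(t, [])
    return paths

def betweenness_oracle(e: BinaryEdgeSet) -> np.ndarray:
    n = e.node_count
    adj = e.to_adjacency()
    score = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score / ((n - 1) * (n - 2) / 2)


def efficiency_oracle(e: BinaryEdgeSet) -> float:
    n = e.node_count
    adj = e.to_adjacency()
    total = 0.0
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t, d in dist.items():
            if t != s:
                total += 1.0 / d
    return total / (n * (n - 1))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestDegree:
    def test_star(self):
        e = BinaryEdgeSet(5, [(0, k) for k in range(1, 5)])
        assert degree(e).values.tolist() == [4, 1, 1, 1, 1]

    def test_empty(self):
        assert degree(BinaryEdgeSet(6, [])).values.tolist() == [0] * 6

    def test_incidence_oracle(self, rng):
        c = random_connected_connectome(rng, 8)
        e = edge_set(c)
        counts = np.zeros(8)
        for i, j in e.edges:
            counts[i] += 1
            counts[j] += 1
        assert np.array_equal(degree(e).values, counts)
        assert degree(e).values.sum() == 2 * len(e)


class TestBetweenness:
    def test_path_graph(self):
        e = BinaryEdgeSet(3, [(0, 1), (1, 2)])
        assert betweenness_centrality(e).values.tolist() == [0.0, 1.0, 0.0]

    def test_complete_graph(self):
        e = BinaryEdgeSet(5, [(i, j) for i in range(5)
                              for j in range(i + 1, 5)])
        assert np.allclose(betweenness_centrality(e).values, 0.0)

    def test_exhaustive_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            c = random_connected_connectome(rng, n)
            e = edge_set(c)
            np.testing.assert_allclose(betweenness_centrality(e).values,
                                       betweenness_oracle(e), atol=1e-12)


class TestGlobalEfficiency:
    def test_complete_binary(self):
        e = BinaryEdgeSet(4, [(i, j) for i in range(4)
                              for j in range(i + 1, 4)])
        assert global_efficiency(e).value == pytest.approx(1.0)

    def test_empty(self):
        assert global_efficiency(BinaryEdgeSet(4, [])).value == 0.0

    def test_path_graph_hand_value(self):
        # pairs at distance {1, 1, 2} -> mean(1, 1, 1/2) = 5/6
        e = BinaryEdgeSet(3, [(0, 1), (1, 2)])
        assert global_efficiency(e).value == pytest.approx(5 / 6)

    def test_inverse_mean_convention(self):
        e = BinaryEdgeSet(3, [(0, 1), (1, 2)])
        # mean distance = (1 + 1 + 2) / 3 -> inverse = 3/4
        v = global_efficiency(e, convention=INVERSE_MEAN).value
        assert v == pytest.approx(3 / 4)

    def test_disconnected_pairs_contribute_zero(self):
        e = BinaryEdgeSet(4, [(0, 1)])
        # ordered pairs: 2 connected at d=1 of 12
        assert global_efficiency(e).value == pytest.approx(2 / 12)

    def test_exhaustive_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            e = edge_set(random_connected_connectome(rng, n))
            assert global_efficiency(e).value == pytest.approx(
                efficiency_oracle(e), abs=1e-12)

    def test_monotone_under_edge_addition(self, rng):
        n = 7
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rng.shuffle(pairs)
        prev = 0.0
        for k in range(len(pairs) + 1):
            v = global_efficiency(BinaryEdgeSet(n, pairs[:k])).value
            assert v >= prev - 1e-12
            prev = v

    def test_weighted_lengths(self):
        c = from_edges(3, {(0, 1): 2, (1, 2): 2})
        tc = apply_absolute(c, 1)
        # edge length 1/2 each: d = {1/2, 1/2, 1} -> mean(2, 2, 1) = 5/3
        v = global_efficiency(tc.kept, weights=tc.masked("NOS")).value
        assert v == pytest.approx(5 / 3)


class TestNodeStrength:
    def test_mean_of_incident_weights(self):
        nos = {(0, 1): 5, (0, 2): 5}
        c = from_edges(3, nos)
        fa = c.weights["FA"].copy()
        fa[0, 1] = fa[1, 0] = 0.4
        fa[0, 2] = fa[2, 0] = 0.6
        c = from_edges(3, nos)
        c.weights["FA"][:] = fa
        tc = apply_absolute(c, 1)
        v = node_strength(tc, "FA")
        assert v.values[0] == pytest.approx(0.5)
        assert v.values[1] == pytest.approx(0.4)

    def test_isolated_node_undefined_not_zero(self):
        c = from_edges(4, {(0, 1): 9, (1, 2): 8, (2, 3): 1})
        tc = apply_absolute(c, 5)  # node 3 disconnects
        v = node_strength(tc, "FA")
        assert 3 in v.undefined_nodes
        assert np.isnan(v.values[3])

    def test_random_oracle(self, rng):
        c = random_connected_connectome(rng, 8)
        fa = np.where(c.nos > 0, rng.uniform(0.1, 0.9, c.nos.shape), 0.0)
        fa = np.triu(fa, 1)
        fa = fa + fa.T
        from conftest import make_connectome
        c = make_connectome(c.nos, fa=fa)
        tc = apply_absolute(c, 1)
        v = node_strength(tc, "FA")
        for i in range(8):
            inc = [fa[i, j] for j in range(8) if c.nos[i, j] > 0]
            if inc:
                assert v.values[i] == pytest.approx(np.mean(inc))
                assert min(inc) - 1e-12 <= v.values[i] <= max(inc) + 1e-12

    def test_invalid_channel(self, rng):
        tc = apply_absolute(random_connected_connectome(rng, 5), 1)
        with pytest.raises(ValueError):
            node_strength(tc, "NOS")


class TestSubjectSummary:
    def test_constant_strength(self):
        c = from_edges(4, {(0, 1): 2, (1, 2): 2, (2, 3): 2}, fa_value=0.7)
        tc = apply_absolute(c, 1)
        ms = mean_strength(tc, "FA")
        assert ms.value == pytest.approx(0.7)
        assert ms.node_count_used == 4

    def test_fixed_density_uses_all_nodes(self, rng):
        c = random_connected_connectome(rng, 10, p=0.7)
        from conftest import make_connectome
        fa = np.where(c.nos > 0, 0.5, 0.0)
        c = make_connectome(c.nos, fa=fa)
        tc = apply_fixed_density(c, 0.3)
        summary = {m.metric_name: m for m in subject_summary(tc)}
        assert summary["mean_strength_FA"].node_count_used == 10
        assert summary["global_efficiency"].node_count_used == 10

    def test_strong_absolute_excludes_flagged_nodes(self):
        c = from_edges(4, {(0, 1): 30, (1, 2): 30, (2, 3): 1})
        fa = c.weights["FA"].copy()
        fa[2, 3] = fa[3, 2] = 0.9
        c.weights["FA"][:] = fa
        tc = apply_absolute(c, 10)
        ms = mean_strength(tc, "FA")
        assert ms.node_count_used == 3
        assert ms.value == pytest.approx(0.5)  # node 3's 0.9 edge excluded

    def test_subject_metric_dispatch(self, rng):
        tc = apply_absolute(random_connected_connectome(rng, 6), 1)
        assert subject_metric(tc, "global_efficiency") == \
            global_efficiency(tc.kept).value
        with pytest.raises(ValueError):
            subject_metric(tc, "clustering")
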
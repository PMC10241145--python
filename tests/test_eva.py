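import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as hst

from elvar import (
    CellGraph,
    EVAParams,
    Partition,
    community_purity,
    eva_partition,
    louvain_partition,
    modularity,
    objective,
    partition_purity,
)
from elvar.eva import DisconnectedGraphError, scores

from .conftest import barbell_graph, clique_pair_graph, random_connected_graph


def brute_force_modularity(graph, membership, gamma=1.0):
    """O(n^2) double-sum evaluation of the modularity definition."""
    A = graph.adjacency.toarray()
    k = graph.node_degrees
    m = graph.total_edge_weight
    total = 0.0
    for v in range(graph.n_nodes):
        for w in range(graph.n_nodes):
            if membership[v] == membership[w]:
                total += A[v, w] - gamma * k[v] * k[w] / (2 * m)
    return total / (2 * m)


def set_partitions(items):
    """All set partitions of a sequence (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_best_Z(graph, alpha, gamma=1.0):
    best = -np.inf
    n = graph.n_nodes
    for blocks in set_partitions(list(range(n))):
        memb = np.empty(n, dtype=int)
        for label, block in enumerate(blocks):
            memb[block] = label
        part = Partition.from_labels(memb, graph)
        Q = modularity(graph, part, gamma)
        P = partition_purity(part)
        P = 0.0 if np.isnan(P) else P
        best = max(best, objective(Q, P, alpha))
    return best


class TestModularity:
    def test_single_community_is_zero(self, two_cliques):
        part = Partition.from_labels(np.zeros(8, dtype=int), two_cliques)
        assert modularity(two_cliques, part) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_singletons(self):
        A = np.ones((3, 3)) - np.eye(3)
        g = CellGraph(sp.csr_matrix(A), np.array(["a", "b", "c"]))
        part = Partition.from_labels([0, 1, 2], g)
        assert modularity(g, part) == pytest.approx(-1 / 3)

    def test_matches_bruteforce_double_sum(self):
        g = barbell_graph()
        part = Partition.from_labels([0, 0, 0, 1, 1, 1], g)
        assert modularity(g, part) == pytest.approx(
            brute_force_modularity(g, part.membership)
        )

    def test_random_partitions_match_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_connected_graph(rng, n=12)
            memb = rng.integers(0, 4, size=12)
            part = Partition.from_labels(memb, g)
            for gamma in (1.0, 0.5):
                assert modularity(g, part, gamma) == pytest.approx(
                    brute_force_modularity(g, part.membership, gamma)
                )


class TestPurity:
    def test_homogeneous_community(self):
        assert community_purity(np.array([5])) == 1.0

    def test_single_attribute_fraction(self):
        assert community_purity(np.array([3, 1])) == pytest.approx(0.75)

    def test_two_attribute_product(self):
        assert community_purity(
            [np.array([3, 1]), np.array([2, 2])]
        ) == pytest.approx(0.375)

    def test_partition_purity_is_unweighted_mean(self):
        part = Partition(
            np.array([0, 0, 0, 0, 1, 1, 1, 1]),
            np.arange(8).astype(str),
            attr_counts={"a": np.array([[4, 0], [2, 2]])},
            attr_values={"a": np.array(["x", "y"])},
        )
        assert partition_purity(part) == pytest.approx((1.0 + 0.5) / 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=hst.lists(
            hst.lists(hst.integers(0, 20), min_size=2, max_size=5),
            min_size=1,
            max_size=3,
        )
    )
    def test_purity_bounds(self, counts):
        # pad so each attribute vector has the same positive total
        mats = [np.array(c) for c in counts if sum(c) > 0]
        if not mats:
            return
        total = max(m.sum() for m in mats)
        mats = [np.append(m, total - m.sum()) for m in mats]
        p = community_purity(mats)
        assert 0 < p <= 1
        if all((m > 0).sum() == 1 for m in mats):
            assert p == 1.0


class TestObjective:
    def test_endpoints_and_mixture(self):
        assert objective(0.3, 0.9, 0.0) == 0.3
        assert objective(0.3, 0.9, 1.0) == 0.9
        assert objective(0.3, 0.9, 0.8) == pytest.approx(0.78)


class TestEvaPartition:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.8])
    def test_recovers_planted_cliques_at_global_optimum(self, alpha):
        g = clique_pair_graph()
        part, sc = eva_partition(g, EVAParams(alpha=alpha, seed=1))
        assert part.n_communities == 2
        assert len(set(part.membership[:4])) == 1
        assert len(set(part.membership[4:])) == 1
        assert sc.Z == pytest.approx(exhaustive_best_Z(g, alpha), abs=1e-9)

    def test_alpha_one_returns_pure_communities_at_optimum(self):
        g = clique_pair_graph()
        part, sc = eva_partition(g, EVAParams(alpha=1.0, seed=2))
        for c in range(part.n_communities):
            assert community_purity(part.attr_counts["side"][c]) == 1.0
        assert sc.Z == pytest.approx(exhaustive_best_Z(g, 1.0), abs=1e-9)

    def test_alpha_zero_identical_to_louvain_same_seed(self, two_cliques):
        p1, _ = eva_partition(
            two_cliques, EVAParams(alpha=0.0, seed=7, node_order="random")
        )
        p2, _ = louvain_partition(two_cliques, seed=7, mode="random")
        assert np.array_equal(p1.membership, p2.membership)

    def test_sequential_mode_deterministic(self, two_cliques):
        p1, _ = louvain_partition(two_cliques, mode="sequential")
        p2, _ = louvain_partition(two_cliques, mode="sequential")
        assert np.array_equal(p1.membership, p2.membership)

    def test_barbell_reaches_exhaustive_maximum(self):
        g = barbell_graph()
        _, sc = louvain_partition(g, mode="sequential")
        assert sc.Q == pytest.approx(exhaustive_best_Z(g, 0.0), abs=1e-9)

    def test_louvain_beats_trivial_partition(self):
        g = random_connected_graph(np.random.default_rng(3), n=25, p=0.2)
        _, sc = louvain_partition(g, mode="sequential")
        assert sc.Q >= 0.0

    def test_disconnected_graph_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        g = CellGraph(sp.csr_matrix(A), np.arange(4).astype(str))
        with pytest.raises(DisconnectedGraphError, match="ensure_connected"):
            louvain_partition(g)

    def test_scores_identity(self, two_cliques):
        part, sc = eva_partition(two_cliques, EVAParams(alpha=0.6, seed=0))
        assert sc.Z == pytest.approx(0.6 * sc.P + 0.4 * sc.Q, abs=1e-12)


class TestOptimizerInvariants:
    def test_trace_is_nondecreasing(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            g = random_connected_graph(rng, n=30, p=0.15)
            _, _, trace = eva_partition(
                g, EVAParams(alpha=0.7, seed=int(rng.integers(1 << 30))),
                return_trace=True,
            )
            assert np.all(np.diff(trace) > -1e-12)

    def test_incremental_delta_matches_full_recompute(self):
        from elvar.eva import _LevelGraph, _State

        rng = np.random.default_rng(9)
        checked = 0
        while checked < 200:
            g = random_connected_graph(rng, n=15, p=0.3)
            mats = []
            _, codes = np.unique(g.node_attributes["attr"], return_inverse=True)
            mat = np.zeros((g.n_nodes, codes.max() + 1), dtype=np.int64)
            mat[np.arange(g.n_nodes), codes] = 1
            mats.append(mat)
            level = _LevelGraph(g.adjacency, np.zeros(g.n_nodes), mats)
            state = _State(level, gamma=1.0)
            alpha = rng.uniform(0, 1)
            for _ in range(20):
                v = int(rng.integers(g.n_nodes))
                a = int(state.comm_of[v])
                weights = state.neighbor_comm_weights(v)
                cands = [b for b in weights if b != a]
                if not cands:
                    continue
                b = int(rng.choice(cands))
                params = EVAParams(alpha=max(alpha, 1e-9), seed=0)
                before = scores(
                    g, Partition.from_labels(state.comm_of.copy(), g), params
                )
                dQ = state.delta_Q(v, a, b, weights.get(a, 0.0), weights[b])
                dP, p_a, p_b, empties = state.delta_P(v, a, b)
                gain = params.alpha * dP + (1 - params.alpha) * dQ
                state.apply_move(v, a, b, weights.get(a, 0.0), weights[b], p_a, p_b, empties)
                after = scores(
                    g, Partition.from_labels(state.comm_of.copy(), g), params
                )
                assert after.Z - before.Z == pytest.approx(gain, abs=1e-9)
                checked += 1

    def test_aggregation_preserves_scores(self):
        from elvar.eva import _LevelGraph, _State, _aggregate, _local_moving

        rng = np.random.default_rng(10)
        for alpha in (0.0, 0.5, 0.9):
            g = random_connected_graph(rng, n=25, p=0.2)
            _, codes = np.unique(g.node_attributes["attr"], return_inverse=True)
            mat = np.zeros((g.n_nodes, codes.max() + 1), dtype=np.int64)
            mat[np.arange(g.n_nodes), codes] = 1
            level = _LevelGraph(g.adjacency, np.zeros(g.n_nodes), [mat])
            state = _State(level, gamma=1.0)
            params = EVAParams(alpha=max(alpha, 1e-9), seed=11)
            _local_moving(state, params, np.random.default_rng(11), None)
            fine_Q, fine_P = state.current_Q(), state.current_P()
            coarse, _ = _aggregate(level, state.comm_of)
            coarse_state = _State(coarse, gamma=1.0)
            assert coarse_state.current_Q() == pytest.approx(fine_Q, abs=1e-9)
            assert coarse_state.current_P() == pytest.approx(fine_P, abs=1e-9)
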
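"""Attribute-aware community detection by generalized modularity.

The partition objective is Z = alpha*P + (1-alpha)*Q, where Q is the
Newman-Girvan modularity with resolution gamma and P is the mean community
purity: for each community, the product across node attributes of the
dominant attribute-value frequency. Optimization follows the two-phase
Louvain scheme — local moving of nodes followed by graph aggregation —
with super-nodes carrying summed attribute-value counts so that the purity
of a coarse partition equals the purity of the induced fine partition
exactly. At alpha = 0 the purity term vanishes and the procedure reduces
to plain Louvain (sequential node order gives the deterministic variant,
random order the stochastic one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .graph import CellGraph

__all__ = [
    "EVAParams",
    "Partition",
    "ClusteringScores",
    "DisconnectedGraphError",
    "modularity",
    "community_purity",
    "partition_purity",
    "objective",
    "scores",
    "eva_partition",
    "louvain_partition",
]


class DisconnectedGraphError(ValueError):
    pass


@dataclass(frozen=True)
class EVAParams:
    """Parameters of the generalized-modularity optimizer.

    alpha : weight of the purity term, in [0, 1]; 0 recovers Louvain.
    gamma : modularity resolution, in (0, 1]; 1 is standard modularity.
    seed : drives the node-visit permutation in random order mode.
    max_passes : cap on local-moving sweeps per aggregation level.
    node_order : 'random' redraws a seeded permutation each pass;
        'sequential' visits nodes in index order (deterministic).
    tol : minimum objective gain for a move to be accepted.
    """

    alpha: float = 0.0
    gamma: float = 1.0
    seed: int = 0
    max_passes: int = 20
    node_order: Literal["sequential", "random"] = "random"
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class Partition:
    """Community assignment per cell plus per-community attribute counts.

    ``attr_counts[name]`` is a (n_communities x n_values) count matrix whose
    rows sum to the community sizes; ``attr_values[name]`` gives the column
    order.
    """

    membership: np.ndarray  # contiguous labels 0..K-1
    cell_ids: np.ndarray
    attr_counts: dict[str, np.ndarray] = field(default_factory=dict)
    attr_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids)
        labels = np.unique(self.membership)
        if not np.array_equal(labels, np.arange(len(labels))):
            _, self.membership = np.unique(self.membership, return_inverse=True)

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_communities)

    @classmethod
    def from_labels(
        cls,
        membership: Sequence[int],
        graph: CellGraph,
        attributes: Sequence[str] | None = None,
    ) -> "Partition":
        part = cls(np.asarray(membership), graph.cell_ids)
        names = list(graph.node_attributes) if attributes is None else attributes
        for name in names:
            vals, codes = np.unique(graph.node_attributes[name], return_inverse=True)
            counts = np.zeros((part.n_communities, len(vals)), dtype=np.int64)
            np.add.at(counts, (part.membership, codes), 1)
            part.attr_counts[name] = counts
            part.attr_values[name] = vals
        return part


@dataclass(frozen=True)
class ClusteringScores:
    Q: float
    P: float
    Z: float
    n_communities: int


def modularity(graph: CellGraph, part: Partition, gamma: float = 1.0) -> float:
    """Modularity Q via per-community edge-weight and degree sums.

    Equals (1/2m) sum_vw [A_vw - gamma k_v k_w / 2m] delta(c_v, c_w) but is
    computed from community aggregates, never the full double sum.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    m = graph.total_edge_weight
    if m <= 0:
        raise ValueError("graph has no edges (m = 0)")
    memb = part.membership
    if len(memb) != graph.n_nodes:
        raise ValueError("partition does not cover the graph")
    coo = graph.adjacency.tocoo()
    same = memb[coo.row] == memb[coo.col]
    intra = coo.data[same].sum()  # ordered pairs: each intra edge twice
    tot = np.bincount(memb, weights=graph.node_degrees, minlength=part.n_communities)
    return float(intra / (2 * m) - gamma * np.sum((tot / (2 * m)) ** 2))


def community_purity(attr_counts) -> float:
    """Purity of one community: product over attributes of max-count / size.

    ``attr_counts`` is one value-count vector per attribute (or a single
    vector for the one-attribute case); every vector sums to the community
    size. Equals 1 iff the community is homogeneous in every attribute.
    """
    if isinstance(attr_counts, (np.ndarray, list, tuple)) and np.ndim(
        attr_counts[0] if len(attr_counts) else attr_counts
    ) == 0:
        attr_counts = [attr_counts]
    purity = 1.0
    for counts in attr_counts:
        counts = np.asarray(counts)
        size = counts.sum()
        if size == 0:
            raise ValueError("community is empty")
        purity *= counts.max() / size
    return float(purity)


def partition_purity(part: Partition) -> float:
    """Unweighted mean of community purity over all communities."""
    if not part.attr_counts:
        return float("nan")
    K = part.n_communities
    total = 0.0
    for c in range(K):
        total += community_purity([m[c] for m in part.attr_counts.values()])
    return total / K


def objective(Q: float, P: float, alpha: float) -> float:
    """Generalized modularity Z = alpha*P + (1-alpha)*Q."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * P + (1.0 - alpha) * Q


def scores(graph: CellGraph, part: Partition, params: EVAParams) -> ClusteringScores:
    """Recompute (Q, P, Z) of a partition from scratch."""
    Q = modularity(graph, part, params.gamma)
    P = partition_purity(part)
    Pz = 0.0 if np.isnan(P) else P
    return ClusteringScores(Q, P, objective(Q, Pz, params.alpha), part.n_communities)


# ---------------------------------------------------------------------------
# optimizer internals
# ---------------------------------------------------------------------------


class _LevelGraph:
    """One aggregation level.

    CSR adjacency without loops; ``loops[v]`` is the internal fine-edge
    weight of super-node v (counted twice in its degree, as for a collapsed
    undirected edge); ``attr`` carries one (n_nodes x n_values) count matrix
    per attribute so coarse purity stays exact.
    """

    __slots__ = ("indptr", "indices", "weights", "loops", "attr", "degrees", "m")

    def __init__(self, adjacency, loops, attr) -> None:
        adjacency = sp.csr_matrix(adjacency)
        self.indptr = adjacency.indptr
        self.indices = adjacency.indices
        self.weights = adjacency.data.astype(float)
        self.loops = np.asarray(loops, dtype=float)
        self.attr = [np.asarray(m, dtype=np.int64) for m in attr]
        self.degrees = np.asarray(adjacency.sum(axis=1)).ravel() + 2.0 * self.loops
        self.m = self.degrees.sum() / 2.0

    @property
    def n_nodes(self) -> int:
        return len(self.loops)


class _State:
    """Mutable community bookkeeping during local moving at one level."""

    def __init__(self, level: _LevelGraph, gamma: float) -> None:
        n = level.n_nodes
        self.level = level
        self.gamma = gamma
        self.comm_of = np.arange(n)
        self.comm_tot = level.degrees.copy()
        self.intra = 2.0 * level.loops.copy()  # ordered-pair internal weight
        self.comm_attr = [m.copy() for m in level.attr]
        if level.attr:
            self.comm_size = level.attr[0].sum(axis=1).copy()
        else:
            self.comm_size = np.ones(n, dtype=np.int64)
        self.nonempty = np.ones(n, dtype=bool)
        self.purity = np.array([self._purity_of(c) for c in range(n)])
        self.sum_purity = float(self.purity.sum())
        self.n_nonempty = n

    def _purity_of(self, c: int) -> float:
        if not self.comm_attr:
            return 0.0
        p = 1.0
        size = self.comm_size[c]
        for mat in self.comm_attr:
            p *= mat[c].max() / size
        return p

    @staticmethod
    def _purity_from(counts_list, size: int) -> float:
        p = 1.0
        for counts in counts_list:
            p *= counts.max() / size
        return p

    def current_Q(self) -> float:
        m = self.level.m
        tot = self.comm_tot
        return float(
            self.intra.sum() / (2 * m) - self.gamma * np.sum((tot / (2 * m)) ** 2)
        )

    def current_P(self) -> float:
        if not self.comm_attr:
            return float("nan")
        return self.sum_purity / self.n_nonempty

    def neighbor_comm_weights(self, v: int) -> dict[int, float]:
        w: dict[int, float] = {}
        lvl = self.level
        comm_of = self.comm_of
        for j in range(lvl.indptr[v], lvl.indptr[v + 1]):
            c = int(comm_of[lvl.indices[j]])
            w[c] = w.get(c, 0.0) + lvl.weights[j]
        return w

    def delta_Q(self, v: int, a: int, b: int, k_va: float, k_vb: float) -> float:
        """Modularity gain of moving v from community a to b."""
        m = self.level.m
        k_v = self.level.degrees[v]
        tot_a_wo = self.comm_tot[a] - k_v
        return (k_vb - k_va) / m - self.gamma * k_v * (
            self.comm_tot[b] - tot_a_wo
        ) / (2 * m * m)

    def delta_P(self, v: int, a: int, b: int):
        """Purity change of moving v a->b.

        Moving a node touches at most two communities; their purity is
        recomputed exactly from attribute counts, and a community that
        empties is dropped from the 1/|C| average.
        Returns (dP, new_purity_a, new_purity_b, a_empties).
        """
        lvl = self.level
        size_v = int(lvl.attr[0][v].sum())
        size_a_new = int(self.comm_size[a]) - size_v
        size_b_new = int(self.comm_size[b]) + size_v
        a_empties = size_a_new == 0
        p_a_new = 0.0
        if not a_empties:
            p_a_new = self._purity_from(
                [mc[a] - mn[v] for mc, mn in zip(self.comm_attr, lvl.attr)],
                size_a_new,
            )
        p_b_new = self._purity_from(
            [mc[b] + mn[v] for mc, mn in zip(self.comm_attr, lvl.attr)],
            size_b_new,
        )
        new_sum = self.sum_purity - self.purity[a] - self.purity[b] + p_a_new + p_b_new
        new_n = self.n_nonempty - (1 if a_empties else 0)
        dP = new_sum / new_n - self.sum_purity / self.n_nonempty
        return dP, p_a_new, p_b_new, a_empties

    def apply_move(self, v, a, b, k_va, k_vb, p_a_new, p_b_new, a_empties) -> None:
        lvl = self.level
        k_v = lvl.degrees[v]
        loop_v = lvl.loops[v]
        self.intra[a] -= 2.0 * (k_va + loop_v)
        self.intra[b] += 2.0 * (k_vb + loop_v)
        self.comm_tot[a] -= k_v
        self.comm_tot[b] += k_v
        if self.comm_attr:
            size_v = int(lvl.attr[0][v].sum())
            for mc, mn in zip(self.comm_attr, lvl.attr):
                mc[a] -= mn[v]
                mc[b] += mn[v]
            self.comm_size[a] -= size_v
            self.comm_size[b] += size_v
            self.sum_purity += p_a_new + p_b_new - self.purity[a] - self.purity[b]
            self.purity[a] = p_a_new
            self.purity[b] = p_b_new
            if a_empties:
                self.nonempty[a] = False
                self.n_nonempty -= 1
        self.comm_of[v] = b


def _local_moving(state, params, rng, trace) -> bool:
    """Sweep nodes, applying the best positive-gain move per node.

    Candidate communities are those of the node's neighbors; ties between
    equal gains break toward the lowest community label. Returns True if
    any move was accepted at this level.
    """
    n = state.level.n_nodes
    alpha = params.alpha
    has_attr = bool(state.comm_attr)
    improved_any = False
    for _ in range(params.max_passes):
        order = rng.permutation(n) if params.node_order == "random" else np.arange(n)
        moved = False
        for v in order:
            v = int(v)
            a = int(state.comm_of[v])
            weights = state.neighbor_comm_weights(v)
            k_va = weights.get(a, 0.0)
            best_gain = 0.0
            best = None
            for b in sorted(weights):
                if b == a:
                    continue
                k_vb = weights[b]
                dQ = state.delta_Q(v, a, b, k_va, k_vb)
                if has_attr:
                    dP, p_a_new, p_b_new, a_empties = state.delta_P(v, a, b)
                else:
                    dP, p_a_new, p_b_new, a_empties = 0.0, 0.0, 0.0, False
                gain = alpha * dP + (1.0 - alpha) * dQ
                if gain > best_gain:
                    best_gain = gain
                    best = (b, k_vb, p_a_new, p_b_new, a_empties)
            if best is not None and best_gain > params.tol:
                b, k_vb, p_a_new, p_b_new, a_empties = best
                state.apply_move(v, a, b, k_va, k_vb, p_a_new, p_b_new, a_empties)
                moved = improved_any = True
                if trace is not None:
                    Pc = state.current_P()
                    trace.append(
                        objective(state.current_Q(), 0.0 if np.isnan(Pc) else Pc, alpha)
                    )
        if not moved:
            break
    return improved_any


def _aggregate(level: _LevelGraph, comm_of: np.ndarray):
    """Collapse communities into super-nodes with summed weights and counts."""
    _, new_of = np.unique(comm_of, return_inverse=True)
    K = int(new_of.max()) + 1
    n = level.n_nodes
    S = sp.csr_matrix((np.ones(n), (np.arange(n), new_of)), shape=(n, K))
    adj = sp.csr_matrix((level.weights, level.indices, level.indptr), shape=(n, n))
    A_new = (S.T @ adj @ S).tocsr()
    loops_new = A_new.diagonal() / 2.0 + np.asarray(S.T @ level.loops).ravel()
    A_new.setdiag(0)
    A_new.eliminate_zeros()
    attr_new = [np.asarray(S.T @ m) for m in level.attr]
    return _LevelGraph(A_new, loops_new, attr_new), new_of


def eva_partition(
    graph: CellGraph,
    params: EVAParams,
    attributes: Sequence[str] | None = None,
    return_trace: bool = False,
):
    """Optimize Z = alpha*P + (1-alpha)*Q over partitions of the cell graph.

    Parameters
    ----------
    graph : connected CellGraph whose node attributes named in
        ``attributes`` (default: all) enter the purity term.
    params : optimizer settings; ``alpha=0`` is plain Louvain.
    return_trace : additionally return the Z value after each accepted
        move (non-decreasing by construction).

    Returns
    -------
    (Partition, ClusteringScores), plus the trace list if requested.
    """
    if not graph.is_connected():
        raise DisconnectedGraphError(
            "graph is disconnected; run ensure_connected first"
        )
    if attributes is None:
        attributes = list(graph.node_attributes)
    if params.alpha > 0 and not attributes:
        raise ValueError("alpha > 0 requires at least one node attribute")

    attr_mats: list[np.ndarray] = []
    for name in attributes:
        _, codes = np.unique(graph.node_attributes[name], return_inverse=True)
        mat = np.zeros((graph.n_nodes, codes.max() + 1), dtype=np.int64)
        mat[np.arange(graph.n_nodes), codes] = 1
        attr_mats.append(mat)

    rng = np.random.default_rng(params.seed)
    level = _LevelGraph(graph.adjacency, np.zeros(graph.n_nodes), attr_mats)
    fine_of = np.arange(graph.n_nodes)
    trace: list[float] | None = [] if return_trace else None

    while True:
        state = _State(level, params.gamma)
        improved = _local_moving(state, params, rng, trace)
        if not improved:
            break
        level, new_of = _aggregate(level, state.comm_of)
        fine_of = new_of[fine_of]
        if level.n_nodes == 1:
            break

    part = Partition.from_labels(fine_of, graph, attributes=attributes)
    sc = scores(graph, part, params)
    if return_trace:
        return part, sc, trace
    return part, sc


def louvain_partition(
    graph: CellGraph,
    gamma: float = 1.0,
    seed: int = 0,
    mode: Literal["sequential", "random"] = "sequential",
):
    """Plain Louvain (alpha = 0); 'sequential' reproduces the deterministic
    benchmark variant, 'random' the stochastic one."""
    params = EVAParams(alpha=0.0, gamma=gamma, seed=seed, node_order=mode)
    return eva_partition(graph, params)
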
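import numpy as np
import pytest
import scipy.sparse as sp

from elvar import CellGraph, CohortSpec, graph_from_expression, simulate_age_cohort


def clique_pair_graph(attr_name: str = "side") -> CellGraph:
    """Two 4-cliques joined by one bridge edge; attribute = clique side."""
    A = np.zeros((8, 8))
    for grp in ([0, 1, 2, 3], [4, 5, 6, 7]):
        for i in grp:
            for j in grp:
                if i != j:
                    A[i, j] = 1
    A[3, 4] = A[4, 3] = 1
    return CellGraph(
        sp.csr_matrix(A),
        np.array([f"c{i}" for i in range(8)]),
        {attr_name: np.array(["x"] * 4 + ["y"] * 4)},
    )


def barbell_graph() -> CellGraph:
    """Two triangles joined by one bridge edge (6 nodes)."""
    A = np.zeros((6, 6))
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                if i != j:
                    A[i, j] = 1
    A[2, 3] = A[3, 2] = 1
    return CellGraph(sp.csr_matrix(A), np.array([f"c{i}" for i in range(6)]))


def random_connected_graph(rng: np.random.Generator, n: int = 20, p: float = 0.25):
    """Erdos-Renyi graph with a random binary attribute, resampled until
    connected."""
    while True:
        A = (rng.random((n, n)) < p).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        g = CellGraph(
            sp.csr_matrix(A),
            np.array([f"c{i}" for i in range(n)]),
            {"attr": rng.choice(["a", "b"], size=n)},
        )
        if g.total_edge_weight > 0 and g.is_connected():
            return g


def mini_cohort_spec(seed: int = 0) -> CohortSpec:
    """Scaled-down cohort (~200 cells, 600 genes) for fast unit tests."""
    return CohortSpec(
        mice=[
            ("mouse0", "1m", 40),
            ("mouse1", "1m", 57),
            ("mouse2", "3m", 10),
            ("mouse3", "3m", 12),
            ("mouse4", "21m", 21),
            ("mouse5", "21m", 28),
            ("mouse6", "30m", 19),
            ("mouse7", "30m", 12),
        ],
        n_genes=600,
        seed=seed,
    )


@pytest.fixture
def two_cliques():
    return clique_pair_graph()


@pytest.fixture(scope="session")
def cohort_graph():
    """Default-design age cohort and its kNN graph (session-scoped: several
    statistical tests reuse it)."""
    expr, ann = simulate_age_cohort(CohortSpec(seed=0))
    graph, _ = graph_from_expression(
        expr,
        ann,
        ["age_group"],
        sample_col="sample_id",
        n_features=500,
        n_pcs=10,
        k=20,
    )
    return graph, ann


@pytest.fixture(scope="session")
def mini_cohort():
    expr, ann = simulate_age_cohort(mini_cohort_spec(seed=3))
    graph, _ = graph_from_expression(
        expr, ann, ["age_group"], sample_col="sample_id",
        n_features=300, n_pcs=8, k=6,
    )
    return graph, ann
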
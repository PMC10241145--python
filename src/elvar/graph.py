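"""Construction of the kNN cell-cell graph from an expression matrix.

The pipeline mirrors the standard single-cell preprocessing recipe:
variable-feature selection, per-gene scaling with clipping, PCA, kNN in
PC space, OR-symmetrization to an undirected unweighted graph, and a
connectivity check that grows k until the graph is a single component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class GraphConstructionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of nonnegative counts or normalized expression."""

    values: sp.spmatrix | np.ndarray  # genes x cells
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values)
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError("gene/cell id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        if self.min() < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        if sp.issparse(self.values):
            return float(self.values.data.min(initial=0.0))
        return float(self.values.min(initial=0.0))

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class Embedding:
    """Cells x components coordinates with per-component variances."""

    coordinates: np.ndarray  # cells x n_components
    component_variances: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.component_variances = np.asarray(self.component_variances, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        if np.any(np.diff(self.component_variances) > 1e-9):
            raise ValueError("component variances must be nonincreasing")

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class CellGraph:
    """Undirected weighted cell-cell graph with per-node categorical attributes.

    ``adjacency`` is symmetric with a zero diagonal; node degrees are
    weighted, and ``total_edge_weight`` is m (half the sum over ordered
    pairs), the denominator of the modularity.
    """

    adjacency: sp.csr_matrix
    cell_ids: np.ndarray
    node_attributes: dict[str, np.ndarray] = field(default_factory=dict)
    sample_ids: np.ndarray | None = None
    k_used: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if self.adjacency.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match adjacency")
        if np.abs(self.adjacency.diagonal()).max(initial=0.0) > 0:
            raise ValueError("adjacency has self-loops; zero the diagonal")
        diff = (self.adjacency - self.adjacency.T)
        if diff.nnz and np.abs(diff.data).max() > 1e-9:
            raise ValueError("adjacency must be symmetric")
        for name, vals in self.node_attributes.items():
            vals = np.asarray(vals)
            if len(vals) != self.n_nodes:
                raise ValueError(f"attribute {name!r} length mismatch")
            self.node_attributes[name] = vals
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != self.n_nodes:
                raise ValueError("sample_ids length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def node_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def total_edge_weight(self) -> float:
        return float(self.adjacency.sum()) / 2.0

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def edge_list(self) -> pd.DataFrame:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame(
            {"node_u": coo.row, "node_v": coo.col, "weight": coo.data}
        )

    def with_attributes(
        self,
        annotations: pd.DataFrame,
        attribute_cols: Sequence[str],
        sample_col: str | None = None,
        cell_id_col: str = "cell_id",
    ) -> "CellGraph":
        """Attach attribute columns from an annotation table, aligned on cell id."""
        ann = annotations.set_index(cell_id_col).loc[self.cell_ids]
        attrs = dict(self.node_attributes)
        for col in attribute_cols:
            attrs[col] = ann[col].to_numpy()
        samples = self.sample_ids
        if sample_col is not None:
            samples = ann[sample_col].to_numpy()
        return CellGraph(self.adjacency, self.cell_ids, attrs, samples, self.k_used)


def choose_k(n_cells: int, floor_min: int = 5, target_ratio: float = 50.0) -> int:
    """Number of nearest neighbors aiming for n_cells / k ~ target_ratio.

    A floor keeps toy-scale graphs connected; k is capped below n_cells.
    """
    if n_cells < 2:
        raise GraphConstructionError("need at least 2 cells to build a graph")
    k = max(floor_min, int(np.round(n_cells / target_ratio)))
    return min(k, n_cells - 1)


def select_features(expr: ExpressionMatrix, n_top: int, n_bins: int = 10) -> np.ndarray:
    """Rank genes by standardized variance and return the top n_top gene ids.

    The variance of each gene is standardized against a binned mean-variance
    trend: genes are grouped into quantile bins of mean expression and each
    gene's variance is divided by its bin's mean variance. Constant genes are
    excluded. Ties break by gene order, so the ranking is deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    X = expr.values
    n_cells = expr.n_cells
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=1)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
        var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)
    else:
        mean = X.mean(axis=1)
        var = X.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(expr.n_genes)
    variable = var > 0
    if not variable.any():
        raise GraphConstructionError("no variable features: all genes constant")
    idx = np.flatnonzero(variable)
    n_bins_eff = min(n_bins, len(idx))
    # quantile bins of the mean; expected variance is the bin average
    order = np.argsort(mean[idx], kind="stable")
    bins = np.array_split(idx[order], n_bins_eff)
    expected = np.ones_like(var)
    for b in bins:
        expected[b] = var[b].mean()
    score = np.where(variable, var / expected, -np.inf)
    if n_top > len(idx):
        warnings.warn(
            f"requested {n_top} features but only {len(idx)} genes vary; "
            "returning all variable genes"
        )
        n_top = len(idx)
    ranked = np.lexsort((np.arange(len(score)), -score))
    return expr.gene_ids[ranked[:n_top]]


def reduce_dims(
    expr: ExpressionMatrix,
    features: Sequence[str],
    n_pc: int,
    clip: float = 10.0,
) -> Embedding:
    """Scale selected genes (z-score, clipped to +/-clip) and run PCA by SVD."""
    features = np.asarray(features)
    pos = pd.Index(expr.gene_ids).get_indexer(features)
    if (pos < 0).any():
        missing = features[pos < 0]
        raise KeyError(f"features not in matrix: {missing[:5]}")
    if n_pc > min(len(features), expr.n_cells):
        raise GraphConstructionError(
            f"n_pc={n_pc} exceeds min(#features, #cells)="
            f"{min(len(features), expr.n_cells)}"
        )
    X = expr.dense()[pos].T.astype(float)  # cells x features
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    Z = Z - Z.mean(axis=0)  # re-center after clipping
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(len(s)):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U[:, :n_pc] * s[:n_pc]
    variances = s**2 / max(expr.n_cells - 1, 1)
    return Embedding(coords, variances[:n_pc], expr.cell_ids)


def build_knn_graph(emb: Embedding, k: int) -> CellGraph:
    """Euclidean kNN in embedding space, OR-symmetrized, unit edge weights.

    Ties in distance break by ascending cell index, so the edge set is
    deterministic. Self-neighbors are excluded and the diagonal zeroed.
    """
    n = emb.n_cells
    if not 1 <= k < n:
        raise GraphConstructionError(f"require 1 <= k < n_cells, got k={k}, n={n}")
    coords = emb.coordinates
    d2 = (
        np.sum(coords**2, axis=1)[:, None]
        + np.sum(coords**2, axis=1)[None, :]
        - 2.0 * coords @ coords.T
    )
    np.fill_diagonal(d2, np.inf)
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=int)
    col_index = np.arange(n)
    for i in range(n):
        order = np.lexsort((col_index, d2[i]))
        cols[i * k : (i + 1) * k] = order[:k]
    adj = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)  # OR-symmetrize, keep weights at 1
    adj.setdiag(0)
    adj.eliminate_zeros()
    return CellGraph(adj, emb.cell_ids, k_used=k)


def ensure_connected(
    graph: CellGraph, emb: Embedding, k: int, k_step: int = 5
) -> CellGraph:
    """Grow k by k_step and rebuild until the kNN graph is one component."""
    g = graph
    while not g.is_connected():
        k = k + k_step
        assert k <= emb.n_cells - 1, (
            "kNN union graph must connect before k reaches n-1"
        )
        k = min(k, emb.n_cells - 1)
        g = build_knn_graph(emb, k)
    g.node_attributes = dict(graph.node_attributes)
    g.sample_ids = graph.sample_ids
    return g


def graph_from_expression(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    attribute_cols: Sequence[str],
    sample_col: str | None = None,
    n_features: int = 500,
    n_pcs: int = 10,
    k: int | None = None,
    clip: float = 10.0,
    k_step: int = 5,
) -> tuple[CellGraph, Embedding]:
    """Full construction path: features -> scaling/PCA -> kNN -> connect."""
    if k is None:
        k = choose_k(expr.n_cells)
    feats = select_features(expr, n_features)
    n_pcs = min(n_pcs, len(feats), expr.n_cells)
    emb = reduce_dims(expr, feats, n_pcs, clip=clip)
    g = build_knn_graph(emb, k)
    g = ensure_connected(g, emb, k, k_step=k_step)
    g = g.with_attributes(annotations, attribute_cols, sample_col=sample_col)
    return g, emb


def graph_from_embedding(
    emb: Embedding,
    annotations: pd.DataFrame,
    attribute_cols: Sequence[str],
    sample_col: str | None = None,
    k: int | None = None,
    k_step: int = 5,
) -> CellGraph:
    """Build the graph from a precomputed (e.g. batch-corrected) embedding."""
    if k is None:
        k = choose_k(emb.n_cells)
    g = build_knn_graph(emb, k)
    g = ensure_connected(g, emb, k, k_step=k_step)
    return g.with_attributes(annotations, attribute_cols, sample_col=sample_col)
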
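"""Readers and writers for the pipeline's file dialects.

Expression input is MatrixMarket (.mtx, genes x cells) with companion
genes/barcodes TSVs, or a dense TSV/CSV with genes in rows. Annotations
are CSV with at least cell_id and sample_id columns. Intermediate
artifacts (edge lists, embeddings, memberships, count tables) are
header-carrying TSVs that round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .graph import CellGraph, Embedding, ExpressionMatrix

__all__ = [
    "read_mtx",
    "read_dense",
    "read_annotations",
    "write_mtx",
    "write_edge_list",
    "read_edge_list",
    "write_embedding",
    "read_embedding",
    "write_membership",
    "read_membership",
]


def read_mtx(
    mtx_path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> ExpressionMatrix:
    """MatrixMarket matrix (genes x cells) with companion id files; the
    companions default to genes.tsv / barcodes.tsv beside the matrix."""
    mtx_path = Path(mtx_path)
    genes_path = Path(genes_path) if genes_path else mtx_path.parent / "genes.tsv"
    barcodes_path = (
        Path(barcodes_path) if barcodes_path else mtx_path.parent / "barcodes.tsv"
    )
    values = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy()
    return ExpressionMatrix(values, genes, cells)


def write_mtx(expr: ExpressionMatrix, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "matrix.mtx", sp.coo_matrix(expr.values))
    pd.Series(expr.gene_ids).to_csv(
        out_dir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(expr.cell_ids).to_csv(
        out_dir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_dense(path: str | Path) -> ExpressionMatrix:
    """Dense TSV/CSV, genes in rows, first column gene ids, header cell ids."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy()
    )


def read_annotations(path: str | Path, cell_id_col: str = "cell_id") -> pd.DataFrame:
    ann = pd.read_csv(path)
    if cell_id_col not in ann.columns:
        raise ValueError(f"annotation file lacks the {cell_id_col!r} column")
    if ann[cell_id_col].duplicated().any():
        raise ValueError("duplicate cell ids in annotations")
    return ann


def write_edge_list(graph: CellGraph, path: str | Path) -> None:
    graph.edge_list().to_csv(path, sep="\t", index=False)


def read_edge_list(
    path: str | Path, cell_ids: np.ndarray, n_nodes: int | None = None
) -> CellGraph:
    edges = pd.read_csv(path, sep="\t")
    n = n_nodes or len(cell_ids)
    u, v, w = edges["node_u"], edges["node_v"], edges["weight"]
    adj = sp.coo_matrix((w, (u, v)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)
    return CellGraph(adj, cell_ids)


def write_embedding(emb: Embedding, path: str | Path) -> None:
    df = pd.DataFrame(
        emb.coordinates,
        index=emb.cell_ids,
        columns=[f"PC{i + 1}" for i in range(emb.coordinates.shape[1])],
    )
    df.index.name = "cell_id"
    with open(path, "w") as fh:
        fh.write("#variances\t" + "\t".join(map(str, emb.component_variances)) + "\n")
        df.to_csv(fh, sep="\t")


def read_embedding(path: str | Path) -> Embedding:
    with open(path) as fh:
        first = fh.readline().strip().split("\t")
        variances = np.array([float(x) for x in first[1:]])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return Embedding(df.to_numpy(), variances, df.index.to_numpy())


def write_membership(memberships: pd.DataFrame, path: str | Path) -> None:
    """Per-run membership table with columns cell_id, run, community."""
    memberships.to_csv(path, sep="\t", index=False)


def read_membership(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
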
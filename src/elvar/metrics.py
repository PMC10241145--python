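"""Evaluation statistics and the undetermined-label reassignment procedure.

Houses the fraction-of-captured-cells diagnostic, the two-tailed Fisher
exact test, the adjusted Rand index, a chi-square test of partition vs
attribute association, and the iterative neighbor-vote reassignment of
undetermined (UD) polarization labels.
"""

from __future__ import annotations

import warnings
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.metrics import adjusted_rand_score

from .enrichment import CellGroups
from .graph import CellGraph

__all__ = [
    "fcapt_cells",
    "fisher_exact_two_tailed",
    "adjusted_rand_index",
    "chisq_partition_test",
    "reassign_undetermined",
]


def fcapt_cells(
    groups: CellGroups,
    annotations: pd.DataFrame,
    value: str,
    condition_col: str,
    cell_id_col: str = "cell_id",
) -> float:
    """Fraction of value-a cells captured by a's enriched cell group:
    |{cells with value a} ∩ {cells in a's group}| / |{cells with value a}|."""
    with_value = annotations.loc[
        annotations[condition_col].astype(str) == str(value), cell_id_col
    ].to_numpy()
    if len(with_value) == 0:
        raise ValueError(f"no cells carry value {value!r}")
    group = groups.groups.get(str(value), np.array([]))
    captured = np.intersect1d(with_value, group)
    return len(captured) / len(with_value)


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table: the sum over all tables
    with the observed margins whose point probability does not exceed the
    observed one. Zero-margin tables return p = 1 with a warning."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("table has a zero margin; p = 1")
        return 1.0
    return float(st.fisher_exact(table)[1])


def adjusted_rand_index(part1: Sequence, part2: Sequence) -> float:
    """Permutation-model adjusted Rand index; 1 for identical partitions
    (including the single-cluster vs single-cluster degenerate case)."""
    part1, part2 = np.asarray(part1), np.asarray(part2)
    if len(part1) != len(part2):
        raise ValueError("partitions must label the same nodes")
    return float(adjusted_rand_score(part1, part2))


def chisq_partition_test(membership: Sequence, attribute: Sequence):
    """Pearson chi-square on the communities x attribute-values table.

    Returns (statistic, p). A one-row or one-column table is independent by
    construction: statistic 0, p 1. Small expected counts are warned about
    but the statistic is still returned.
    """
    table = pd.crosstab(np.asarray(membership), np.asarray(attribute)).to_numpy()
    if table.size == 0:
        raise ValueError("empty contingency table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, expected = st.chi2_contingency(table, correction=False)
    if expected.min() < 1:
        warnings.warn("expected cell count < 1; chi-square may be inaccurate")
    return float(stat), float(p)


def _multinomial_exact_p(counts: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p: total probability of outcomes
    no more likely than the observed one (enumeration; small n only)."""
    n = int(counts.sum())
    k = len(counts)
    p_obs = st.multinomial.pmf(counts, n, probs)
    total = 0.0
    for combo in _compositions(n, k):
        p = st.multinomial.pmf(combo, n, probs)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def _gof_p(counts: np.ndarray, probs: np.ndarray, exact_max_n: int = 10) -> float:
    n = counts.sum()
    if n == 0:
        return 1.0
    probs = np.asarray(probs, dtype=float)
    keep = probs > 0
    if not keep.all():
        if counts[~keep].sum() > 0:
            return 0.0
        counts, probs = counts[keep], probs[keep]
    probs = probs / probs.sum()
    if n <= exact_max_n:
        return _multinomial_exact_p(np.asarray(counts), probs)
    stat, p = st.chisquare(counts, f_exp=n * probs)
    return float(p)


def reassign_undetermined(
    graph: CellGraph,
    labels: Sequence[str],
    p_thresh: float = 0.05,
    prop_diff: float = 0.2,
    max_iter: int = 20,
    undetermined: str = "UD",
    denominator: str = "all",
) -> tuple[np.ndarray, list[int]]:
    """Iteratively reassign undetermined cells to the determined label that
    dominates their graph neighborhood.

    Each iteration, every UD cell's neighbor label counts are tested
    against the current global label frequencies (exact multinomial for
    <= 10 neighbors, chi-square goodness of fit otherwise). Cells with
    p < p_thresh whose M1/M2 neighbor proportions differ by more than
    ``prop_diff`` are reassigned to the majority determined label.
    Reassignments within an iteration are applied simultaneously; the loop
    stops at ``max_iter`` or at a fixed point. Determined cells are never
    relabeled; isolated cells never reassigned.

    ``denominator='all'`` computes the M1/M2 proportions over all
    neighbors (UD included); 'determined' uses only determined neighbors.

    Returns (final labels, per-iteration reassignment counts).
    """
    labels = np.asarray(labels, dtype=object).copy()
    if len(labels) != graph.n_nodes:
        raise ValueError("labels length must match graph nodes")
    determined = sorted(set(labels) - {undetermined})
    if len(determined) != 2:
        raise ValueError("expected exactly two determined labels plus UD")
    la, lb = determined
    adj = graph.adjacency
    changes: list[int] = []
    categories = [la, lb, undetermined]
    for _ in range(max_iter):
        freq = np.array([(labels == c).mean() for c in categories])
        to_flip: list[tuple[int, str]] = []
        for v in np.flatnonzero(labels == undetermined):
            nbrs = adj.indices[adj.indptr[v] : adj.indptr[v + 1]]
            if len(nbrs) == 0:
                continue
            nl = labels[nbrs]
            counts = np.array([(nl == c).sum() for c in categories])
            if denominator == "all":
                denom = len(nbrs)
            else:
                denom = counts[0] + counts[1]
            if denom == 0:
                continue
            prop_a, prop_b = counts[0] / denom, counts[1] / denom
            if abs(prop_a - prop_b) <= prop_diff:
                continue
            if _gof_p(counts, freq) < p_thresh:
                to_flip.append((v, la if counts[0] > counts[1] else lb))
        for v, lab in to_flip:
            labels[v] = lab
        changes.append(len(to_flip))
        if not to_flip:
            break
    return labels, changes
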
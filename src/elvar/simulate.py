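"""Synthetic single-cell count data with a planted perturbed state.

The generators emulate the benchmark designs used throughout the package's
validation: a sparse negative-binomial base count matrix; a "perturbed"
cell state created by injecting nonzero values (resampled from the
matrix's empirical nonzero distribution) into a fixed pool of otherwise
silent genes, planting a weak co-expression signal; a single-condition
200-cell design; and a multi-mouse age cohort in which the perturbed-state
frequency rises from 0.25 in young to 0.5 in old animals. Robustness
helpers inject false positives into the cell-state annotation and flip
sample condition labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .graph import ExpressionMatrix

__all__ = [
    "CohortSpec",
    "simulate_base_counts",
    "perturb_cells",
    "simulate_single_condition",
    "simulate_age_cohort",
    "inject_annotation_fp",
    "flip_sample_labels",
]


def _default_mice() -> list[tuple[str, str, int]]:
    return [
        ("mouse0", "1m", 201),
        ("mouse1", "1m", 284),
        ("mouse2", "3m", 51),
        ("mouse3", "3m", 60),
        ("mouse4", "21m", 104),
        ("mouse5", "21m", 138),
        ("mouse6", "30m", 94),
        ("mouse7", "30m", 61),
    ]


@dataclass
class CohortSpec:
    """Design of the multi-mouse age cohort.

    Defaults: 8 mice (two replicates per age group at 1, 3, 21 and 30
    months) contributing 993 cells in total, a perturbed-state frequency
    of 0.25 in young (1m, 3m) and 0.5 in old (21m, 30m) groups, 2000 genes
    at desk scale, and a 50-gene silent pool of which 20 genes per
    perturbed cell receive injected expression.
    """

    mice: list[tuple[str, str, int]] = field(default_factory=_default_mice)
    young_groups: tuple[str, ...] = ("1m", "3m")
    old_groups: tuple[str, ...] = ("21m", "30m")
    young_freq: float = 0.25
    old_freq: float = 0.5
    n_genes: int = 2000
    sparsity: float = 0.9
    pool_size: int = 50
    genes_per_cell: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.young_freq, self.old_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError("perturbation frequencies must lie in [0, 1]")
        if self.pool_size < self.genes_per_cell:
            raise ValueError("pool_size must be >= genes_per_cell")
        if sum(n for _, _, n in self.mice) <= 0:
            raise ValueError("cohort must contain cells")

    @property
    def n_cells(self) -> int:
        return sum(n for _, _, n in self.mice)


def simulate_base_counts(
    n_genes: int,
    n_cells: int,
    sparsity_target: float = 0.9,
    seed: int = 0,
    dispersion: float = 0.5,
) -> ExpressionMatrix:
    """Sparse base counts: log-normal gene means, NB2 counts per gene.

    Gene means are rescaled so the expected zero fraction matches
    ``sparsity_target``; the realized zero fraction lands within about
    +/-0.05 of the target.
    """
    if not 0.0 < sparsity_target < 1.0:
        raise ValueError("sparsity_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    base_means = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)

    def expected_zero_fraction(log_scale: float) -> float:
        mu = base_means * np.exp(log_scale)
        return np.mean((dispersion / (dispersion + mu)) ** dispersion)

    try:
        log_scale = brentq(
            lambda s: expected_zero_fraction(s) - sparsity_target, -20.0, 20.0
        )
    except ValueError:
        warnings.warn(
            "sparsity target infeasible for drawn gene means; retuning means"
        )
        base_means = np.full(n_genes, 1.0)
        log_scale = brentq(
            lambda s: expected_zero_fraction(s) - sparsity_target, -30.0, 30.0
        )
    means = base_means * np.exp(log_scale)
    p = dispersion / (dispersion + means)
    counts = rng.negative_binomial(dispersion, p[:, None], size=(n_genes, n_cells))
    values = sp.csr_matrix(counts)
    gene_ids = np.array([f"gene{i}" for i in range(n_genes)])
    cell_ids = np.array([f"cell{i}" for i in range(n_cells)])
    return ExpressionMatrix(values, gene_ids, cell_ids)


def _silent_genes(expr: ExpressionMatrix) -> np.ndarray:
    totals = np.asarray(abs(expr.values).sum(axis=1)).ravel()
    return np.flatnonzero(totals == 0)


def _force_silent_pool(expr: ExpressionMatrix, pool_size: int) -> ExpressionMatrix:
    """Zero out the lowest-abundance genes (uniformly across cells) until at
    least ``pool_size`` genes are silent. A fixed silent-gene complement is
    a normal feature of real count matrices; forcing it keeps the injection
    pool well defined at any simulated scale."""
    silent = _silent_genes(expr)
    deficit = pool_size - len(silent)
    if deficit <= 0:
        return expr
    totals = np.asarray(expr.values.sum(axis=1)).ravel()
    totals[silent] = -1  # already silent, keep out of the ranking
    order = np.argsort(totals, kind="stable")
    to_zero = [g for g in order if totals[g] >= 0][:deficit]
    values = expr.values.tolil()
    for g in to_zero:
        values.rows[g] = []
        values.data[g] = []
    return ExpressionMatrix(values.tocsr(), expr.gene_ids, expr.cell_ids)


def perturb_cells(
    expr: ExpressionMatrix,
    cell_ids,
    pool_size: int = 50,
    genes_per_cell: int = 20,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Inject a weak co-expression signal into the chosen cells.

    A fixed pool of ``pool_size`` genes silent across *all* cells is drawn
    once; each perturbed cell receives exactly ``genes_per_cell`` pool
    genes set to values resampled from the matrix's empirical nonzero
    distribution. Unperturbed cells are untouched.

    Returns the perturbed matrix and the pool gene ids.
    """
    rng = np.random.default_rng(seed)
    silent = _silent_genes(expr)
    if len(silent) < pool_size:
        raise ValueError(
            f"need {pool_size} all-zero genes for the pool, found {len(silent)}"
        )
    pool = rng.choice(silent, size=pool_size, replace=False)
    if sp.issparse(expr.values):
        nonzero_values = expr.values.data[expr.values.data != 0]
    else:
        nonzero_values = expr.values[expr.values != 0]
    if len(nonzero_values) == 0:
        raise ValueError("matrix has no nonzero values to resample from")
    cell_pos = pd.Index(expr.cell_ids).get_indexer(np.asarray(cell_ids))
    if (cell_pos < 0).any():
        raise KeyError("some cell_ids not present in the matrix")
    values = expr.values.tolil(copy=True) if sp.issparse(expr.values) else expr.values.copy()
    for c in cell_pos:
        genes = rng.choice(pool, size=genes_per_cell, replace=False)
        draws = rng.choice(nonzero_values, size=genes_per_cell, replace=True)
        for g, x in zip(genes, draws):
            values[g, c] = x
    if sp.issparse(expr.values):
        values = values.tocsr()
    out = ExpressionMatrix(values, expr.gene_ids, expr.cell_ids)
    return out, expr.gene_ids[np.sort(pool)]


def simulate_single_condition(
    seed: int = 0,
    n_genes: int = 20138,
    n_cells: int = 200,
    n_perturbed: int = 100,
    sparsity: float = 0.9,
    pool_size: int = 50,
    genes_per_cell: int = 20,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Single-sample design: n_cells cells, n_perturbed of them in the
    perturbed state P, the rest normal N. Defaults mirror the 20138-gene x
    200-cell benchmark; pass smaller dimensions for desk-scale work."""
    if n_perturbed > n_cells:
        raise ValueError("n_perturbed cannot exceed n_cells")
    rng = np.random.default_rng(seed)
    expr = simulate_base_counts(n_genes, n_cells, sparsity, seed=seed)
    expr = _force_silent_pool(expr, pool_size)
    perturbed = rng.choice(expr.cell_ids, size=n_perturbed, replace=False)
    expr, _pool = perturb_cells(
        expr, perturbed, pool_size, genes_per_cell, seed=seed + 1
    )
    state = np.where(np.isin(expr.cell_ids, perturbed), "P", "N")
    ann = pd.DataFrame(
        {"cell_id": expr.cell_ids, "sample_id": "sample0", "state": state}
    )
    return expr, ann


def _round_half_even(x: float) -> int:
    return int(np.round(x))  # numpy rounds half to even


def _quota_allocation(counts: np.ndarray, quota: int) -> np.ndarray:
    """Split an integer quota across mice proportionally to their cell
    counts (largest-remainder rule)."""
    raw = counts / counts.sum() * quota
    base = np.floor(raw).astype(int)
    remainder = quota - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def simulate_age_cohort(
    spec: CohortSpec | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Multi-mouse cohort with an age-dependent perturbed-state frequency.

    Perturbed-cell quotas are computed per age group as
    round-half-even(freq x group cell total) and allocated to the group's
    mice proportionally, then injected via :func:`perturb_cells`. The
    annotation table carries cell_id, sample_id (mouse), age_group and
    state (N/P).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    expr = simulate_base_counts(
        spec.n_genes, spec.n_cells, spec.sparsity, seed=spec.seed
    )
    expr = _force_silent_pool(expr, spec.pool_size)

    mice = pd.DataFrame(spec.mice, columns=["mouse_id", "age_group", "n_cells"])
    cell_mouse = np.repeat(mice["mouse_id"].to_numpy(), mice["n_cells"].to_numpy())
    cell_age = np.repeat(mice["age_group"].to_numpy(), mice["n_cells"].to_numpy())
    ann = pd.DataFrame(
        {
            "cell_id": expr.cell_ids,
            "sample_id": cell_mouse,
            "age_group": cell_age,
            "state": "N",
        }
    )

    freq_of = {}
    for g in spec.young_groups:
        freq_of[g] = spec.young_freq
    for g in spec.old_groups:
        freq_of[g] = spec.old_freq

    perturbed_cells: list[str] = []
    for age, block in mice.groupby("age_group", sort=False):
        freq = freq_of.get(age)
        if freq is None:
            continue
        group_total = int(block["n_cells"].sum())
        quota = _round_half_even(freq * group_total)
        if quota > group_total:
            raise ValueError(f"quota {quota} exceeds group size {group_total}")
        per_mouse = _quota_allocation(block["n_cells"].to_numpy(), quota)
        for (_, mouse), q in zip(block.iterrows(), per_mouse):
            cells = ann.loc[ann["sample_id"] == mouse["mouse_id"], "cell_id"].to_numpy()
            perturbed_cells.extend(rng.choice(cells, size=q, replace=False))

    expr, _pool = perturb_cells(
        expr,
        perturbed_cells,
        spec.pool_size,
        spec.genes_per_cell,
        seed=spec.seed + 1,
    )
    ann.loc[ann["cell_id"].isin(perturbed_cells), "state"] = "P"
    return expr, ann


def inject_annotation_fp(
    annotations: pd.DataFrame,
    attribute_of_interest: str,
    fpr: float,
    seed: int = 0,
    target_value: str | None = None,
) -> pd.DataFrame:
    """Relabel a seeded fraction ``fpr`` of target-value cells to another
    value of the attribute of interest (exact quota round(fpr * n_target));
    all other columns are untouched."""
    if not 0.0 <= fpr <= 0.5:
        raise ValueError("fpr must lie in [0, 0.5]")
    ann = annotations.copy()
    if fpr == 0.0:
        return ann
    rng = np.random.default_rng(seed)
    values = ann[attribute_of_interest].unique()
    if target_value is None:
        target_value = values[0]
    others = [v for v in values if v != target_value]
    if not others:
        raise ValueError("need at least two attribute values to inject FPs")
    target_idx = ann.index[ann[attribute_of_interest] == target_value].to_numpy()
    n_flip = int(np.round(fpr * len(target_idx)))
    flip = rng.choice(target_idx, size=n_flip, replace=False)
    ann.loc[flip, attribute_of_interest] = rng.choice(others, size=n_flip)
    return ann


def flip_sample_labels(
    annotations: pd.DataFrame,
    condition_col: str,
    n_flips_per_side: int = 1,
    seed: int = 0,
    sample_col: str = "sample_id",
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Swap the condition labels of sample pairs drawn from the two sides
    of a binary condition; the swap applies to every cell of each flipped
    sample. Explicit ``pairs`` of (sample_a, sample_b) override the seeded
    draw. Returns the modified annotations and the flip log."""
    ann = annotations.copy()
    cond_of = ann.drop_duplicates(sample_col).set_index(sample_col)[condition_col]
    values = cond_of.unique()
    if len(values) != 2:
        raise ValueError("sample-label flips require a binary condition")
    side_a = cond_of.index[cond_of == values[0]].to_numpy()
    side_b = cond_of.index[cond_of == values[1]].to_numpy()
    if pairs is None:
        if n_flips_per_side > min(len(side_a), len(side_b)):
            raise ValueError("n_flips_per_side exceeds a side's sample count")
        rng = np.random.default_rng(seed)
        chosen_a = rng.choice(side_a, size=n_flips_per_side, replace=False)
        chosen_b = rng.choice(side_b, size=n_flips_per_side, replace=False)
        pairs = list(zip(chosen_a, chosen_b))
    log: list[tuple[str, str]] = []
    for sa, sb in pairs:
        ca, cb = cond_of[sa], cond_of[sb]
        ann.loc[ann[sample_col] == sa, condition_col] = cb
        ann.loc[ann[sample_col] == sb, condition_col] = ca
        log.append((str(sa), str(sb)))
    return ann, log
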
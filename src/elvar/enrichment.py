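"""Selection of condition-enriched communities.

For each community and each clustering-attribute value, a one-tailed
binomial test asks whether the community contains more cells of that value
than expected from the global value frequency. Communities passing a
Bonferroni threshold of 0.05 / (n_communities * n_values) are flagged, and
the cells of all communities flagged for a value are merged into that
value's cell group; cells of unflagged communities are discarded as noisy
neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .eva import Partition

__all__ = [
    "EnrichmentTable",
    "CellGroups",
    "binomial_enrichment",
    "select_enriched",
    "build_cell_groups",
]


@dataclass
class EnrichmentTable:
    """One-tailed binomial enrichment p-values, communities x values."""

    pvalues: pd.DataFrame  # index: community, columns: attribute values
    counts: pd.DataFrame
    sizes: np.ndarray
    p0: pd.Series  # global value frequencies, sums to 1
    attribute: str

    @property
    def bonferroni_threshold(self) -> float:
        return 0.05 / (self.pvalues.shape[0] * self.pvalues.shape[1])


@dataclass
class CellGroups:
    """Per attribute value, the merged cells of its enriched communities."""

    groups: dict[str, np.ndarray]  # value -> cell ids
    provenance: dict[str, list[int]] = field(default_factory=dict)
    attribute: str = ""

    def all_cells(self) -> np.ndarray:
        """Union of cells across all groups (cells surviving enrichment)."""
        if not self.groups:
            return np.array([], dtype=object)
        return np.unique(np.concatenate([g for g in self.groups.values()]))


def binomial_enrichment(part: Partition, attribute: str) -> EnrichmentTable:
    """Exact one-tailed binomial tail p = P(X >= x) with X ~ Bin(|c|, p0).

    p0 is the global frequency of each attribute value over all graph cells.
    The exact tail is used throughout since communities can be small.
    """
    if attribute not in part.attr_counts:
        raise KeyError(f"partition carries no counts for attribute {attribute!r}")
    counts = part.attr_counts[attribute]
    values = part.attr_values[attribute]
    sizes = counts.sum(axis=1)
    n_total = sizes.sum()
    p0 = counts.sum(axis=0) / n_total
    # P(X >= x) = sf(x - 1); x = 0 gives 1 exactly
    pvals = binom.sf(counts - 1, sizes[:, None], p0[None, :])
    communities = np.arange(part.n_communities)
    return EnrichmentTable(
        pvalues=pd.DataFrame(pvals, index=communities, columns=values),
        counts=pd.DataFrame(counts, index=communities, columns=values),
        sizes=sizes,
        p0=pd.Series(p0, index=values),
        attribute=attribute,
    )


def select_enriched(table: EnrichmentTable, level: float = 0.05) -> pd.DataFrame:
    """Flag (community, value) pairs with p strictly below the Bonferroni
    threshold level / (n_communities * n_values)."""
    threshold = level / (table.pvalues.shape[0] * table.pvalues.shape[1])
    return table.pvalues < threshold


def build_cell_groups(
    flags: pd.DataFrame,
    part: Partition,
    exclusive: bool = False,
    table: EnrichmentTable | None = None,
) -> CellGroups:
    """Merge member cells of flagged communities into per-value groups.

    With ``exclusive=True`` a community flagged for several values is
    assigned only to the value with the smallest p (requires ``table``);
    by default it contributes its cells to every value it is enriched for.
    """
    flags = flags.copy()
    if exclusive:
        if table is None:
            raise ValueError("exclusive assignment needs the EnrichmentTable")
        for c in flags.index:
            hit = flags.loc[c]
            if hit.sum() > 1:
                best = table.pvalues.loc[c][hit].idxmin()
                flags.loc[c] = False
                flags.loc[c, best] = True
    groups: dict[str, np.ndarray] = {}
    provenance: dict[str, list[int]] = {}
    attribute = table.attribute if table is not None else ""
    for value in flags.columns:
        comms = [int(c) for c in flags.index[flags[value]]]
        provenance[str(value)] = comms
        if not comms:
            warnings.warn(f"no communities enriched for value {value!r}; empty group")
            groups[str(value)] = np.array([], dtype=part.cell_ids.dtype)
            continue
        mask = np.isin(part.membership, comms)
        groups[str(value)] = part.cell_ids[mask]
    return CellGroups(groups=groups, provenance=provenance, attribute=attribute)
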
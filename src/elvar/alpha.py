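"""Selection of the purity parameter alpha by a three-criterion sweep.

EVA is run repeatedly over a grid of alpha values; an alpha qualifies if
(1) the 95% quantile (over runs) of the ratio of its community count to
the deterministic Louvain baseline is at least 1.5, (2) its mean purity is
at least 75% of the mean purity at the largest grid alpha, and (3) its
mean modularity is at least 75% of the mean modularity at the smallest
grid alpha. The intersection typically bounds alpha within a band; the
largest qualifying alpha is returned, since within the admissible band
higher purity is the method's point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eva import EVAParams, eva_partition, louvain_partition
from .graph import CellGraph

__all__ = ["SweepStats", "AlphaSelectionError", "run_sweep", "select_alpha"]

DEFAULT_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


class AlphaSelectionError(ValueError):
    def __init__(self, message: str, sets: dict[str, list[float]]):
        super().__init__(message)
        self.sets = sets


@dataclass
class SweepStats:
    """Per-alpha run vectors of community count, Q, P and Z, plus the
    deterministic Louvain baseline community count."""

    grid: np.ndarray
    n_runs: int
    n_communities: dict[float, np.ndarray]
    Q: dict[float, np.ndarray]
    P: dict[float, np.ndarray]
    Z: dict[float, np.ndarray]
    baseline_n_communities: int

    def __post_init__(self) -> None:
        self.grid = np.sort(np.asarray(self.grid, dtype=float))
        if self.baseline_n_communities <= 0:
            raise ValueError("baseline community count must be positive")
        for d in (self.n_communities, self.Q, self.P, self.Z):
            for a in self.grid:
                if len(d[float(a)]) != self.n_runs:
                    raise ValueError("run vectors must have length n_runs")

    def frame(self) -> pd.DataFrame:
        rows = []
        for a in self.grid:
            a = float(a)
            for r in range(self.n_runs):
                rows.append(
                    {
                        "alpha": a,
                        "run": r,
                        "n_communities": self.n_communities[a][r],
                        "Q": self.Q[a][r],
                        "P": self.P[a][r],
                        "Z": self.Z[a][r],
                    }
                )
        return pd.DataFrame(rows)


def run_sweep(
    graph: CellGraph,
    attributes: Sequence[str] | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    n_runs: int = 100,
    gamma: float = 1.0,
    seed: int = 0,
) -> SweepStats:
    """Run EVA ``n_runs`` times per grid alpha with per-run seeds derived
    deterministically from the master seed; the baseline community count
    comes from one deterministic sequential Louvain run."""
    grid = np.sort(np.asarray(grid, dtype=float))
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("alpha grid must lie strictly inside (0, 1)")
    if n_runs < 2:
        raise ValueError("need at least 2 runs per grid point")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid) * n_runs)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    nc: dict[float, np.ndarray] = {}
    Q: dict[float, np.ndarray] = {}
    P: dict[float, np.ndarray] = {}
    Z: dict[float, np.ndarray] = {}
    i = 0
    for a in grid:
        a = float(a)
        nc[a] = np.empty(n_runs)
        Q[a] = np.empty(n_runs)
        P[a] = np.empty(n_runs)
        Z[a] = np.empty(n_runs)
        for r in range(n_runs):
            params = EVAParams(alpha=a, gamma=gamma, seed=seeds[i], node_order="random")
            _, sc = eva_partition(graph, params, attributes=attributes)
            nc[a][r], Q[a][r], P[a][r], Z[a][r] = sc.n_communities, sc.Q, sc.P, sc.Z
            i += 1
    _, base_sc = louvain_partition(graph, gamma=gamma, mode="sequential")
    return SweepStats(
        grid=grid,
        n_runs=n_runs,
        n_communities=nc,
        Q=Q,
        P=P,
        Z=Z,
        baseline_n_communities=base_sc.n_communities,
    )


def select_alpha(
    stats: SweepStats,
    q: float = 0.95,
    ratio_min: float = 1.5,
    purity_frac: float = 0.75,
    mod_frac: float = 0.75,
) -> float:
    """Apply the three selection criteria and return the largest qualifying
    alpha. Raises :class:`AlphaSelectionError` (carrying the three sets)
    when the intersection is empty; the thresholds can then be relaxed."""
    grid = [float(a) for a in stats.grid]
    a_hi, a_lo = grid[-1], grid[0]
    ref_P = float(np.mean(stats.P[a_hi]))
    ref_Q = float(np.mean(stats.Q[a_lo]))
    s1 = [
        a
        for a in grid
        if np.quantile(stats.n_communities[a] / stats.baseline_n_communities, q)
        >= ratio_min
    ]
    s2 = [a for a in grid if np.mean(stats.P[a]) >= purity_frac * ref_P]
    s3 = [a for a in grid if np.mean(stats.Q[a]) >= mod_frac * ref_Q]
    intersection = sorted(set(s1) & set(s2) & set(s3))
    if not intersection:
        raise AlphaSelectionError(
            "no alpha satisfies all three criteria; the three thresholds "
            f"(q={q}, ratio_min={ratio_min}, purity_frac={purity_frac}, "
            f"mod_frac={mod_frac}) can be altered",
            sets={"cluster_ratio": s1, "purity": s2, "modularity": s3},
        )
    return intersection[-1]
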
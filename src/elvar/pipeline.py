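"""End-to-end orchestration of the four pipeline stages.

Graph construction (or loading a precomputed embedding), optional alpha
sweep, repeated seeded attribute-aware clustering runs, enrichment-based
cell-group selection, and per-run negative-binomial DA testing, with a
manifest recording seeds, parameters and versions so any run can be
reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import run_sweep, select_alpha
from .da import results_frame, run_da
from .enrichment import binomial_enrichment, build_cell_groups, select_enriched
from .eva import EVAParams, eva_partition
from .graph import CellGraph, graph_from_embedding, graph_from_expression
from .io import (
    read_annotations,
    read_dense,
    read_embedding,
    read_mtx,
    write_edge_list,
    write_membership,
)
from .metrics import fcapt_cells

logger = logging.getLogger("elvar")

_KNOWN_KEYS = {
    "input",
    "genes",
    "barcodes",
    "annotations",
    "precomputed_embedding",
    "clustering_attribute",
    "attribute_of_interest",
    "sample_column",
    "n_features",
    "n_pcs",
    "k",
    "alpha",
    "gamma",
    "n_runs",
    "seed",
    "order",
    "sweep_runs",
    "enrichment_level",
    "output_dir",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Flat configuration for a full pipeline run.

    ``alpha`` may be a number in (0, 1], 0 for the Louvain benchmark, or
    the string 'auto' to trigger the selection sweep.
    """

    annotations: str
    clustering_attribute: str
    attribute_of_interest: str
    input: str | None = None
    genes: str | None = None
    barcodes: str | None = None
    precomputed_embedding: str | None = None
    sample_column: str = "sample_id"
    n_features: int = 500
    n_pcs: int = 10
    k: int | None = None
    alpha: float | str = 0.8
    gamma: float = 1.0
    n_runs: int = 20
    seed: int = 0
    order: str = "random"
    sweep_runs: int = 20
    enrichment_level: float = 0.05
    output_dir: str = "elvar_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if isinstance(self.alpha, str) and self.alpha != "auto":
            raise ValueError("alpha must be a number or 'auto'")
        if self.input is None and self.precomputed_embedding is None:
            raise ValueError("either input or precomputed_embedding is required")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Aggregated output of a multi-run pipeline execution."""

    selected_alpha: float
    z_table: pd.DataFrame  # one row per (run, attribute-of-interest value)
    summary: pd.DataFrame  # per value: median z across runs
    fcapt: pd.DataFrame  # per (run, condition value): fraction captured
    memberships: pd.DataFrame
    scores: pd.DataFrame
    sweep: pd.DataFrame | None = None
    manifest: dict[str, Any] = field(default_factory=dict)


def run_analysis(
    graph: CellGraph,
    annotations: pd.DataFrame,
    clustering_attribute: str,
    attribute_of_interest: str,
    sample_column: str = "sample_id",
    alpha: float | str = 0.8,
    gamma: float = 1.0,
    n_runs: int = 20,
    seed: int = 0,
    order: str = "random",
    sweep_runs: int = 20,
    enrichment_level: float = 0.05,
) -> PipelineResult:
    """Clustering -> enrichment -> DA testing on a prepared cell graph."""
    sweep_frame = None
    if alpha == "auto":
        logger.info("selecting alpha by sweep (%d runs per grid point)", sweep_runs)
        stats = run_sweep(
            graph,
            attributes=[clustering_attribute],
            n_runs=sweep_runs,
            gamma=gamma,
            seed=seed,
        )
        alpha = select_alpha(stats)
        sweep_frame = stats.frame()
        logger.info("selected alpha = %.2f", alpha)
    alpha = float(alpha)

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_runs)]
    condition_values = np.unique(annotations[clustering_attribute].astype(str))

    z_rows, fc_rows, memb_rows, score_rows = [], [], [], []
    for run, run_seed in enumerate(run_seeds):
        params = EVAParams(
            alpha=alpha, gamma=gamma, seed=run_seed, node_order=order  # type: ignore[arg-type]
        )
        part, sc = eva_partition(graph, params, attributes=[clustering_attribute])
        table = binomial_enrichment(part, clustering_attribute)
        flags = select_enriched(table, level=enrichment_level)
        groups = build_cell_groups(flags, part, table=table)
        score_rows.append(
            {
                "run": run,
                "seed": run_seed,
                "alpha": alpha,
                "Q": sc.Q,
                "P": sc.P,
                "Z": sc.Z,
                "n_communities": sc.n_communities,
            }
        )
        memb_rows.append(
            pd.DataFrame(
                {"cell_id": part.cell_ids, "run": run, "community": part.membership}
            )
        )
        for value in condition_values:
            try:
                fc = fcapt_cells(groups, annotations, value, clustering_attribute)
            except ValueError:
                fc = np.nan
            fc_rows.append({"run": run, "condition": value, "fcapt": fc})
        try:
            results = run_da(
                groups,
                annotations,
                attribute_of_interest,
                clustering_attribute,
                sample_col=sample_column,
            )
        except ValueError as exc:
            logger.warning("run %d: DA testing skipped (%s)", run, exc)
            results = []
        for r in results:
            z_rows.append(
                {
                    "run": run,
                    "t": r.value,
                    "z": r.z,
                    "z_wald": r.z_wald,
                    "z_lrt": r.z_lrt,
                    "gamma_t": r.gamma,
                    "p_wald": r.p_wald,
                    "p_lrt": r.p_lrt,
                    "method": r.method_used,
                }
            )

    z_table = pd.DataFrame(z_rows)
    if len(z_table):
        summary = (
            z_table.groupby("t")["z"]
            .median()
            .rename("median_z")
            .reset_index()
            .sort_values("median_z", key=abs, ascending=False, ignore_index=True)
        )
    else:
        summary = pd.DataFrame(columns=["t", "median_z"])
    return PipelineResult(
        selected_alpha=alpha,
        z_table=z_table,
        summary=summary,
        fcapt=pd.DataFrame(fc_rows),
        memberships=pd.concat(memb_rows, ignore_index=True),
        scores=pd.DataFrame(score_rows),
        sweep=sweep_frame,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven execution: load inputs, build the graph, run the
    analysis, and persist all artifacts plus a manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        t0 = time.time()
        annotations = read_annotations(config.annotations)
        stage = "graph-construction"
        if config.precomputed_embedding:
            emb = read_embedding(config.precomputed_embedding)
            graph = graph_from_embedding(
                emb,
                annotations,
                [config.clustering_attribute],
                sample_col=config.sample_column,
                k=config.k,
            )
        else:
            path = Path(config.input)
            if path.suffix == ".mtx":
                expr = read_mtx(path, config.genes, config.barcodes)
            else:
                expr = read_dense(path)
            graph, emb = graph_from_expression(
                expr,
                annotations,
                [config.clustering_attribute],
                sample_col=config.sample_column,
                n_features=config.n_features,
                n_pcs=config.n_pcs,
                k=config.k,
            )
        write_edge_list(graph, out / "edges.tsv")
        logger.info("graph: %d nodes, m=%g", graph.n_nodes, graph.total_edge_weight)
        stage = "analysis"
        result = run_analysis(
            graph,
            annotations,
            config.clustering_attribute,
            config.attribute_of_interest,
            sample_column=config.sample_column,
            alpha=config.alpha,
            gamma=config.gamma,
            n_runs=config.n_runs,
            seed=config.seed,
            order=config.order,
            sweep_runs=config.sweep_runs,
            enrichment_level=config.enrichment_level,
        )
        stage = "write-outputs"
        write_membership(result.memberships, out / "membership.tsv")
        result.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        result.z_table.to_csv(out / "da_results.tsv", sep="\t", index=False)
        result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        result.fcapt.to_csv(out / "fcapt.tsv", sep="\t", index=False)
        if result.sweep is not None:
            result.sweep.to_csv(out / "sweep.tsv", sep="\t", index=False)
        manifest = {
            "version": __version__,
            "config": {k: v for k, v in asdict(config).items()},
            "selected_alpha": result.selected_alpha,
            "seed": config.seed,
            "n_cells": int(graph.n_nodes),
            "k_used": graph.k_used,
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        result.manifest = manifest
        return result
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
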
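# elvar

Cell-attribute-aware community detection and differential abundance (DA)
testing for single-cell RNA-seq.

## The problem

Shifts in cell-state or cell-subtype proportions across biological
conditions — aging, disease stage, treatment — are often small effects
buried in noisy single-cell data: cells cluster by broad cell type, not by
condition, so topology-only clustering (Louvain) yields communities that
mix conditions and dilute the downstream abundance signal. `elvar`
addresses this by folding the condition label itself into the clustering
objective, then testing abundance changes of a second attribute with
replicate-aware negative-binomial regression.

## The method

Given a kNN cell-cell graph, the partition is chosen by maximizing a
generalized modularity

```
Z = α·P + (1 − α)·Q
```

where `Q` is Newman–Girvan modularity with resolution γ,

```
Q = (1/2m) Σ_vw [A_vw − γ k_v k_w / 2m] δ(c_v, c_w),
```

and `P` is the mean community purity: for each community, the product over
node attributes of the dominant attribute-value frequency. At `α = 0` the
optimizer is exactly Louvain; growing α trades edge density for condition
homogeneity. Optimization is the classic two-phase local-moving /
aggregation scheme, with super-nodes carrying attribute count vectors so
purity stays exact at every level.

The pipeline then

1. **selects α** by a three-criterion sweep (community count ≥ 1.5× the
   Louvain baseline at the 95% run quantile; mean purity ≥ 75% of its
   level at α = 0.9; mean modularity ≥ 75% of its level at α = 0.1),
2. **keeps communities enriched** for a condition value (one-tailed
   binomial test against the global frequency, Bonferroni threshold
   `0.05 / (n_communities × n_values)`), discarding noisy neighborhoods,
3. **tests differential abundance**: per-sample counts `n_st` of each
   attribute-of-interest value `t` follow
   `n_st ~ NB(μ_st, φ_t)`, `log μ_st = α_t + β_t·log(n_s) + γ_t·v_s`,
   with `n_s` the sample's retained-cell total and `v_s` its ordinal
   condition code. The sign and significance of `γ_t` is the DA readout
   (Wald test with a small-sample dispersion correction; likelihood-ratio
   fallback for degenerate fits).

A synthetic-data module generates the benchmark designs used throughout
the tests: sparse negative-binomial counts with a "perturbed" cell state
planted by injecting expression into a pool of silent genes, in a
multi-mouse age cohort whose perturbed-state frequency rises from 0.25
(young) to 0.5 (old).

## Worked example

```python
from elvar import CohortSpec, graph_from_expression, run_analysis, simulate_age_cohort

expr, ann = simulate_age_cohort(CohortSpec(seed=0))     # 2000 genes x 993 cells, 8 mice
graph, _ = graph_from_expression(expr, ann, ["age_group"],
                                 sample_col="sample_id",
                                 n_features=500, n_pcs=10, k=20)
result = run_analysis(graph, ann, "age_group", "state", alpha=0.8,
                      n_runs=5, seed=0)
print(result.summary)
```

prints

```
t  median_z
P     5.063
N    -4.572
```

The planted perturbed state `P` (frequency 0.25 in young mice, 0.5 in
old) is recovered as a strongly positive age association and the normal
state as its mirror image; each z is the condition coefficient `γ_t` of
the per-mouse count regression, so |z| > 2 indicates a significant
abundance shift. Running the same analysis with `alpha=0` (plain Louvain
communities) gives median z near 0 on most seeds — the purity term is
what makes the age-coherent communities, and hence the signal,
recoverable. `examples/` holds one short script per capability
(simulation, clustering, α selection, DA testing, label reassignment).

A thin CLI mirrors the stages:

```sh
elvar simulate cohort --seed 0 --out-dir data/
elvar graph --input data/matrix.mtx --annotations data/annotations.csv --attribute age_group
elvar sweep --edges edges.tsv --annotations data/annotations.csv --attribute age_group
elvar run --config config.yaml
```

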
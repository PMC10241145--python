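# Methods

## Model

The package partitions a kNN cell-cell graph by maximizing the
generalized modularity `Z = α·P + (1 − α)·Q` and then tests whether the
composition of a second cell attribute shifts across the conditions used
in the clustering.

**Modularity.** `Q = (1/2m) Σ_vw [A_vw − γ k_v k_w / 2m] δ(c_v, c_w)`,
with edge weights `A_vw` (unit weights for the kNN graph), weighted
degrees `k_v`, total edge weight `m`, and resolution `γ ∈ (0, 1]`
(default 1, which keeps the α = 0 limit exactly the classic Louvain
objective). `Q` is always evaluated from per-community edge and degree
sums, never the O(n²) double sum; the test suite checks the two against
each other on small graphs.

**Purity.** Each community `c` scores
`P_c = Π_attributes max_value(count) / |c|` — the product across node
attributes of its dominant attribute-value frequency — and
`P = mean_c P_c`, an unweighted mean over communities. `P_c = 1` iff the
community is homogeneous in every attribute. The pipeline default uses a
single clustering attribute (age group, disease stage); the product form
supports several.

**Interpretation of α.** α weights condition homogeneity against edge
density. Because the graph itself is built only from expression, purity
can only act within the topological degrees of freedom the graph leaves
open; empirically Q degrades slowly until α approaches 1 (the α-sweep
example shows Q ≈ 0.45 at α = 0.8 vs 0.50 at α = 0.1, collapsing only at
α = 0.9).

## Optimizer

Two-phase local moving + aggregation:

- Singleton initialization; nodes are visited in a seeded random
  permutation redrawn each pass (`node_order="random"`), or in index
  order for the deterministic benchmark variant (`"sequential"`, which
  reproduces classic deterministic Louvain at α = 0).
- A node moves to the neighboring community with the largest ΔZ if
  ΔZ > tol (tol = 1e-12); ties break toward the lowest community label,
  making runs reproducible given the seed. ΔQ uses the standard
  degree-sum increment; ΔP is recomputed exactly from the attribute
  counts of the (at most two) affected communities, with a community that
  empties dropped from the 1/|C| average. The equality of these
  increments with full recomputation is property-tested over hundreds of
  random moves.
- Aggregation collapses communities into super-nodes carrying summed edge
  weights, self-loop weight (internal edge weight, counted twice in the
  degree) and summed attribute-count vectors, so coarse-level (Q, P, Z)
  equal the fine-level values to machine precision (asserted at 1e-9).
- Passes repeat until a full pass makes no move (cap 20 per level);
  levels repeat until no move improves Z. Z is non-decreasing across
  accepted moves by construction.

On small planted graphs (two cliques plus a bridge) the optimizer attains
the exhaustive maximum of Z over all set partitions for any α; this is a
structural sanity check, not a global-optimality guarantee in general.

## α selection

EVA-style sweeps run the optimizer `n_runs` times per α over the grid
0.1–0.9 (step 0.1). Three sets are formed: α whose 95% run-quantile of
`n_communities / baseline` is ≥ 1.5 (baseline = the deterministic
sequential-Louvain community count, a single well-defined number); α with
mean purity ≥ 75% of the mean purity at the top grid point; α with mean
modularity ≥ 75% of the mean modularity at the bottom grid point. The
first two criteria bound α from below, the third from above; from the
intersection the **largest** α is returned, since within the admissible
band condition homogeneity is the method's point. An empty intersection
raises an error carrying all three sets so thresholds can be relaxed
deliberately.

## Enrichment and cell groups

For community `c` and condition value `a`, the enrichment p-value is the
exact binomial tail `P(X ≥ x_ca)` with `X ~ Bin(|c|, p0_a)` and `p0_a`
the value's global frequency over the analyzed cells (communities can be
small, so no normal approximation). Flags require
`p < 0.05 / (n_communities × n_values)` strictly. Cells of all
communities flagged for a value form that value's cell group; cells of
unflagged communities are dropped. A community enriched for several
values contributes to each by default; `exclusive=True` assigns it to its
minimum-p value only.

## Differential abundance regression

Counts are tallied over the union of all retained (enriched) cells: per
sample `s`, the count `n_st` of each attribute-of-interest value `t`,
zero-filled, with total `n_s` and the sample's ordinal condition code
`v_s` (ranks of the clustering-attribute values; values with numeric
prefixes such as `1m < 3m < 18m` are ordered numerically; user codes can
override). Samples with no retained cells are dropped — `log n_s` must be
finite.

The model is NB2: `n_st ~ NB(μ_st, φ_t)` with
`log μ_st = α_t + β_t log(n_s) + γ_t v_s`. `β_t` is a free coefficient,
not a fixed offset, so the normalization strength is estimated.
Coefficients and the reported dispersion `φ_t` are maximum likelihood
(statsmodels NB2, Poisson-initialized BFGS retry on failure).

**Small-sample Wald inference.** With replicate-level data the per-fit
sample count is small (often ≈ 10); the normal-reference ML Wald test is
then anti-conservative (empirically ~0.12 rejection at nominal 0.05 in
the calibration simulations). The reported standard error therefore uses
a Pearson moment dispersion with residual-df correction — solve
`Σ (y − μ̂)² / (μ̂ + μ̂²/φ) = n − p` for φ, invert the expected
information with the resulting weights — and the Wald p is referred to a
t distribution with `n − 3` df. This is the convention R itself applies
to GLMs with estimated dispersion; measured type-I error is 0.05 at the
criterion design (12 samples, 4 conditions, φ = 2). The LRT p (dropping
`v_s`) and its signed normal quantile `z_lrt` are always reported, and
become the primary statistic whenever the Wald machinery degenerates —
an all-zero condition (separation) or a non-finite/collapsed standard
error. Because the corrected Wald z is deliberately more conservative
than the ML LRT z, the two agree in sign but differ by a median ≈ 0.6 at
n = 40; they are not interchangeable numerically.

Note that doubling all counts and totals is *not* an exact invariance of
the ML fit (the likelihood surface changes, not just the systematic
part); `γ̂_t` moves at finite-sample order (~3e-3 at n = 40), which the
tests bound loosely rather than at machine precision.

## Synthetic data

`simulate_base_counts` draws log-normal gene means (σ = 1.5), rescales
them so the expected NB2 zero fraction (gene dispersion 0.5) matches the
sparsity target (default 0.9), and samples counts. This emulates the
sparsity and mean-variance shape of droplet scRNA-seq counts but none of
its gene-length, library-size or batch structure — passing tests show the
method's behavior under its own generative assumptions, not performance
on any real tissue.

`perturb_cells` picks a fixed pool (default 50) of genes silent in every
cell, and for each perturbed cell sets a random subset (default 20) of
pool genes to values resampled from the matrix's empirical nonzero
distribution — a weak planted co-expression signal that leaves marginal
expression statistics intact. When the base draw leaves fewer than
pool-size silent genes, the lowest-abundance genes are zeroed uniformly
across cells first (a silent complement is a normal feature of count
matrices, and the perturbation is only defined against one).

Designs: a single-condition set (200 cells, 100 perturbed; gene dimension
20138 by default, smaller for desk-scale work) and the multi-mouse
cohort — 8 mice, cell counts (201, 284, 51, 60, 104, 138, 94, 61) across
age groups (1m, 1m, 3m, 3m, 21m, 21m, 30m, 30m), perturbation frequency
0.25 in young (1m/3m) and 0.5 in old (21m/30m) groups. Quotas are
computed per age group as round-half-even(freq × group total) and split
across the group's mice by largest remainder, so realized group
frequencies match the design as closely as integers allow (young: exactly
149/596 = 0.25; old: 199/397 ≈ 0.501). Cohort gene dimension defaults to
2000 at desk scale.

Robustness helpers: `inject_annotation_fp` relabels an exact quota
`round(fpr × n_target)` of target-state cells; `flip_sample_labels` swaps
the condition of sample pairs, touching every cell of each flipped
sample.

## Graph construction

Feature selection ranks genes by standardized variance — variance divided
by the mean variance of the gene's decile-of-mean bin — a deliberately
simple stand-in for loess-based variance stabilization; only the ranking
matters downstream, and it is deterministic (ties by gene order).
Selected genes are z-scored, clipped at ±10, re-centered, and reduced by
exact SVD with a sign convention (largest-magnitude loading positive) for
reproducibility. kNN uses Euclidean distance in PC space with ties broken
by ascending cell index, OR-symmetrization, unit weights, zero diagonal.
`choose_k` targets n/50 with a floor of 5 (the ratio rule alone gives
unusably small k on toy inputs); if the graph is disconnected, k grows by
5 and the graph is rebuilt until connected. The distance metric and
symmetrization rule of upstream toolkits are not specified exactly
anywhere; OR-symmetrized Euclidean kNN is this package's declared
convention.

## Label reassignment (M1/M2/UD)

Undetermined cells are iteratively reassigned to a determined label when
their neighbor label counts are inconsistent with the current global
label frequencies (exact multinomial test for ≤ 10 neighbors — total
probability of outcomes no likelier than observed — chi-square
goodness-of-fit above) at p < 0.05, *and* the M1/M2 neighbor proportions
differ by more than 0.2. Proportions are computed over all neighbors (UD
included) by default; `denominator="determined"` switches to determined
neighbors only, since the defining proportion is ambiguous between the
two readings. Updates within an iteration are simultaneous, determined
cells are never touched, and iteration stops at a fixed point or 20
rounds.

## Problem sizes and numerical choices

Statistical tests and the acceptance script run at desk scale by choice:
cohorts of 993 cells × 2000 genes, 20 seeded cohorts for the power
comparison, 10-run sweeps, 200-replicate recovery and 1000-replicate
calibration simulations. Scores are recomputed from scratch for every
returned partition as a cross-check on the incremental bookkeeping.
Degenerate inputs: empty graphs, disconnected graphs, all-constant
expression, zero-margin contingency tables, empty cell groups and
all-zero regression conditions all raise or warn explicitly rather than
propagating NaNs.

## Known limitations

- The optimizer is greedy; no refinement phase (Leiden-style) is
  implemented, and global optimality is only verified on toy graphs.
- Purity uses the dominant-value frequency only; it is insensitive to the
  composition of the non-dominant remainder.
- The regression treats condition codes as equally spaced ordinals; a
  genuinely nonlinear dose-response is out of model.
- The synthetic generator does not emulate batch effects, doublets,
  ambient RNA, or realistic library-size variation; batch correction is
  deliberately out of scope (precomputed embeddings are accepted
  instead).
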
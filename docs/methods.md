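# Methods

This note documents the models, rules and numerical choices implemented in
`regpattern`, in the order the pipeline applies them, followed by the
synthetic-data model and known limitations.

## Preprocessing

**QC.** Cells are removed when total UMI < 600, UMI per detected gene < 1.2,
detected genes < 500, or mitochondrial fraction > 0.05 (mitochondrial genes
identified by a configurable id prefix, default `mt-`; the boundary words
"less than" / "greater than" are implemented as strict inequalities). Genes
are removed when detected in fewer than 20 cells or in more than 60% of all
cells, evaluated on the surviving cells. The report counts removals per rule;
a cell violating two rules is counted under both.

**Normalization.** `ln(1 + s · count / cell_total)` with scale s = 10 000.
The raw counts layer is kept: detection fractions ("expressing" = raw count
> 0), identity rules and binary marking operate on counts, while all means,
distances and rank tests use the normalized layer.

**Variable genes.** Per gene, mean and dispersion are computed on the
back-transformed scale (mean of `expm1(normalized)`; dispersion =
log(variance/mean)), genes are binned into 300 equal-count bins by mean, and
dispersion is robust-z-scored within each bin (median and MAD with the
1.4826 normal-consistency factor; a zero-MAD bin maps above-median genes to
+inf so they remain selectable). Selected: mean in (0.0125, 8) and z ≥ 0.5.
Fewer genes than bins reduces the bin count with a warning.

## Distances and similarity calls

**Profile distance.** d(i,j) = (1 − r)/2 with r the sample Pearson
correlation between cluster mean profiles over the chosen gene set (≥ 3
genes; a zero-variance profile is an error naming the cluster — never
silently imputed). The matrix is validated after every computation:
symmetric, zero diagonal, range [0, 1].

**Subsample-averaged distance.** Each of `reps` (default 20) draws
⌊fraction·|G|⌋ genes (default fraction 0.8) without replacement and the
distance matrices are averaged elementwise. Averaging happens on distances,
not on downstream calls; a per-rep voting aggregation is available in the
robustness check (`aggregate="votes"`) for users who prefer to aggregate the
calls themselves.

**Similarity calls.** For pair (i,j) the default ("conditional") reference
set S is every distance involving i or j, including d(i,j) itself, so
|S| = 2(n−2)+1. The pair is *similar* iff its ascending competition rank in S
is ≤ ⌈0.10·|S|⌉ and *dissimilar* iff the rank is > ⌊0.20·|S|⌋; ranks between
the two boundaries are *intermediate* and never support a pattern. Ties share
the minimum rank, so a set of tied boundary distances is called similar as a
whole (a constant matrix therefore makes every pair similar, with a
degenerate-input warning). The "global" mode ranks against all n(n−1)/2
distances with the same boundaries, and a `per_cluster_and` flag requires the
rank condition within each member's own distance set separately.

**Sensitivity of the rank rule.** The dissimilar zone covers 80% of the
reference set, so for a pair whose distance is statistically exchangeable
with the background (exactly the situation of a convergent pair's TF
distance when TF profiles are unrelated), the dissimilar call has ≈ 0.81
sensitivity per pair — by construction, not by estimation error. Conversely
the similar zone admits any background pair with probability ≈ 0.10, which
on n clusters with unstructured background produces of order
0.1·n(n−1)/2 spurious similar calls. Users should read population-level
pattern sets as high-recall/low-precision and rely on the intersection with
the sister analysis (below) for precision; even then, a planted convergent
or divergent pair is lost with ~0.19 probability whenever its "unrelated"
block is genuinely exchangeable with background. This noise floor is a
property of the published rule and is reported honestly by
`evaluate_recovery` and the robustness check rather than smoothed over.

## Trees

**Ward dendrograms.** Agglomeration uses the ward.D Lance–Williams update on
the raw (un-squared) dissimilarities, matching R's `hclust(method="ward.D")`
(verified against R on frozen fixtures); this differs from the
squared-input ward.D2 that scipy's `ward` implements, which is why the
algorithm is written out here. Ties in the minimum distance are broken by
the lexicographically smallest pair of cluster representatives
(representative = smallest leaf label), so trees are bit-reproducible.
Heights are non-decreasing; sub-epsilon floating dips are clamped.

**Cutting and cherries.** `cut_tree` removes merges above the cut height
(the published major-cell-type cut is 0.42) and returns connected
components. Sister pairs are the cherries — internal nodes with two leaf
children; they are disjoint by construction and invariant to child order.

**Bootstrap support.** Genes (columns) are resampled with replacement;
BP(clade) is the fraction of resampled trees containing the clade's exact
leaf set. The multiscale variant resamples at relative sizes
r ∈ {0.5, …, 1.4} (step 0.1) and fits z(r) = d·√r + c/√r, where
z(r) = √r·Φ⁻¹(1−BP_r), by weighted least squares with delta-method binomial
weights; AU = 1 − Φ(d − c). BPs are clamped to [1/(2B), 1−1/(2B)] before the
probit transform; clades with BP 0 or 1 at every scale get that boundary AU
with a `degenerate` flag instead of an exception. "Strongly supported" means
AU strictly greater than 0.9. A zero-variance profile within a bootstrap
resample is treated as uncorrelated (r = 0) rather than aborting the
replicate.

**Tree discordance.** The default metric ("cid") matches the two trees'
internal-node bipartitions one-to-one (assignment solver, root excluded) to
maximize total shared mutual clustering information, normalized by the mean
self-information of the two trees; distance = 1 − normalized shared
information, snapped to exactly 0 below 1e−12 so identical topologies
compare equal. "rf" is Robinson–Foulds on non-trivial bipartitions
normalized by 2(n−3). Matching nodes are internal nodes (root excluded)
whose induced leaf sets are identical in both trees; shared cherries are
listed. Neither metric is claimed to reproduce any particular published
distance value, whose metric was not fully specified.

## Patterns

Population-level patterns: matched = similar/similar, convergent =
similar(effector)/dissimilar(TF), divergent = dissimilar(effector)/
similar(TF); any intermediate call leaves the pair unclassified (a
conservative rule — an ambiguous call never invents a pattern). Sister
patterns use cherry membership in the two trees the same way. The
intersection keeps a pair's pattern only when both strategies assign the
same pattern — pattern equality, not mere pair co-occurrence. Robustness
re-derives population patterns from subsample-averaged distances and
reports, per pattern, the fraction of full-run pairs that keep their
pattern.

## Differential expression and RBPs

`find_markers` tests genes detected (count > 0) in ≥ 10% of either group
whose detection fractions differ by ≥ 0.25, with a two-sided Wilcoxon
rank-sum on the normalized layer and Bonferroni correction over the genes
actually tested (never the full panel). Groups of ≤ 8 cells each use the
exact null distribution by full enumeration (midranks handle ties); larger
groups use the normal approximation with tie and continuity corrections.
`mean_log_diff` is the difference of group means of the normalized layer — a
simple, monotone surrogate for a fold-change, documented as not identical to
one. Marker ranking: ascending adjusted p, ties by descending
|mean_log_diff|.

Identity assignment ("over 5% of cells expressing, or mean UMI of expressing
cells over 2") uses strict inequalities; the binary ON/OFF marking rule
("cutoff of 5% … or UMI = 2") names its boundary as attainable and is
inclusive — the two rules are intentionally distinct. The marker UMI average
is the mean total marker UMI per marker-expressing cell.

Pattern-specific RBPs are RBP-category genes significantly differential
(adjusted p < 0.05 by default; the published analysis states the filters but
not its significance cutoff, so alpha is configurable) in at least one pair
of a pattern and in no pair of any other pattern — the sets are disjoint by
construction. Reuse frequency counts jointly over all pairs regardless of
pattern: |RBPs in ≥ 2 pairs| / |RBPs in ≥ 1 pair|. Target-category
proportions pool the target-table rows of a pattern's RBPs; RBPs absent
from the table are excluded with a warning and a pattern with no rows gets
an undefined (None) proportion, never zero.

## Mapping, stability, marking

NNLS uses the Lawson–Hanson active-set solver; solutions satisfy the KKT
conditions to 1e−8 (asserted in tests against a projected-gradient oracle).
Cross-dataset mapping decomposes each query cluster's mean profile over the
pooled top-20 reference markers (each reference cluster must retain ≥ 3
markers after intersecting with the query's genes). Jaccard stability
subsamples 80% of cells, re-clusters with any user-supplied callable, and
scores each original cluster by its maximum Jaccard index against any new
cluster (the per-rep max convention, no bipartite matching), averaged over
20 reps; stable means mean ≥ 0.6 (median also reported). The built-in
reference clusterer (k-means on top principal components) exists to exercise
the stability machinery and is documented as a stand-in, not a product
clusterer. Morphology–cluster correspondence decomposes each ON/OFF
morphology column over the cluster columns by NNLS and flags coefficients
> 0.1 after row-normalization (the correspondence cutoff is not published;
0.1 is the default and configurable).

## Synthetic data

The generator plants the statistical structure the pattern analysis assumes.
Per gene block (TF / effector / RBP / other), every cluster's latent profile
is a standard-normal vector built from a block-wide latent (weight
√rho_background), an optional pair-shared latent (weight
√(rho_similar − rho_background)) and cluster-private noise; planted pairs
share the pair latent on their correlated blocks (matched: TF + effector;
convergent: effector; divergent: TF). The RBP and residual blocks track
effector similarity — matched and convergent pairs share them, divergent
pairs do not — and each divergent pair additionally receives a +1.5
log-scale offset on 10 designated RBP genes (alternating which cluster is
high), so divergent pairs carry recoverable differential RBP markers.
Latent profiles map to the non-negative log-expression scale by
`softplus(mu_g + 1.2·z)` with per-gene baselines mu_g ~ N(0, 0.5); the
monotone transform attenuates realized Pearson correlations slightly below
the latent targets (0.95 → ≈ 0.95 within pairs, 0 → ≈ 0.1–0.2 between
unrelated clusters, from the shared baselines).

Counts are negative binomial: cell library sizes are lognormal with mean
2 000 UMI (sigma 0.3, roughly the scale of real droplet libraries), per-gene
means are the library size times the cluster's linear-scale profile
(expm1 of the log profile, normalized to proportions), and the NB size
parameter defaults to 2 (variance = mu + mu²/size; large size approaches
Poisson). Defaults — 30 clusters, 3 planted pairs per pattern, 500 TF + 500
effector + 100 RBP + 100 other genes, rho_similar 0.95, rho_background 0,
200 cells per cluster — are the standard study conditions used by the
analysis scripts and the acceptance script.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-cycle structure, gene–gene correlation within blocks beyond
the planted latents, and any region/neurotransmitter metadata structure.
Passing tests on this generator therefore show that the rules and statistics
behave as specified under their own assumptions, not that the biological
conclusions transfer to any particular real dataset.

## Problem sizes and determinism

The analysis scripts and tests run the standard study (6 000 cells × 1 300
genes per seed) in a few seconds per seed; bootstrap support uses 100–200
replicates in tests and the acceptance script derives every stage seed from
the single top-level seed via a stable hash (`derive_seed(seed, stage)`), so
stages are independently reproducible and identical inputs give identical
outputs. The pipeline recomputes everything on each run; outputs are small
tables, so no resume/caching layer is provided.

## Interface note

The package is a library plus numbered analysis drivers; there is no console
entry point. `run_pipeline` is the single-call orchestration, and the
`analysis/` scripts are the shell-facing surface.
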
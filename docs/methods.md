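# Methods

This note documents the models, statistics, defaults and design choices
behind `cellprograms`, and what the synthetic-data validation does and does
not establish about real data.

## Cellular-program discovery

A cohort is summarized as a composition matrix: for sample s and cell type
t at a chosen annotation level, the infiltration rate is
p(s, t) = n(s, t)/n(s). Rows lie on the simplex by construction. Samples
with fewer than `min_cells_per_sample` cells (default 50) are dropped:
proportions estimated from a handful of cells have sampling error larger
than the between-program differences being sought.

Sample similarity is Spearman's ρ between composition rows (average ranks
for ties). Rank correlation is deliberate: it is invariant to any strictly
increasing per-sample transform, so differences in how compositions were
normalized or truncated cannot change the clustering. Samples whose
composition is exactly constant across types have undefined ρ; they are
flagged and must be resolved (usually removed) before clustering.

Programs are found by agglomerative clustering with **complete linkage**
on the distance d = 1 − ρ, cutting the dendrogram into exactly k clusters.
d = 1 − ρ is the simplest monotone transform of the correlation; complete
linkage produces compact clusters and makes the k-cut nest inside the
(k−1)-cut (a property the tests assert). k is a required analyst choice —
no automatic selection is performed — but `program_stability` reports the
mean adjusted Rand index between the full-data partition and partitions on
bootstrap-resampled sample sets to support it. Program ids CP1..CPk are
assigned in decreasing cluster-size order with ties broken by the
lexicographically smallest member, purely to make labels deterministic.

Pseudo-bulk profiles (per-group means of log-normalized expression) are
clustered with the same Spearman/complete-linkage construction to relate
cell groups transcriptionally.

## R_o/e enrichment

For a cluster × program table of observed cell counts O, expected counts
are the chi-square independence expectations E(i, j) = n_i· n_·j / n, and
R_o/e(i, j) = O(i, j)/E(i, j). No continuity or small-count correction is
applied; the ratio is reported raw, and enrichment calls use the strict
rule R_o/e > 1. The statistic is invariant to rescaling all counts, and the
expectation-weighted row mean of R_o/e is identically 1 — both properties
are regression-tested, and the implementation is checked against a
loop-based oracle on random tables. Zero rows/columns are excluded (their
expectations vanish). The annotation level used for the rows is a
parameter; no level is hard-wired.

## Sample entropy

Heterogeneity of a sample over (CNV-)cluster labels is Shannon entropy
H(s) = −Σ_c p(c|s) log p(c|s) with 0·log 0 := 0, natural log by default and
base 2 on request; the normalized variant divides by log of the number of
labels observed in that sample (defined as 0 for single-label samples), so
it is 1 exactly when labels are uniform over ≥ 2 clusters. Group contrasts
of entropy (or any per-sample statistic) use the Kruskal–Wallis H test with
tie correction, delegated to scipy.

## Signatures and module scores

Markers are selected per cluster by a two-sided Wilcoxon rank-sum test of
the cluster vs. all other cells on the log-normalized layer (asymptotic,
tie-corrected), with Benjamini–Hochberg adjustment across genes. The
effect size is log2((mean_target + ε)/(mean_rest + ε)) with ε = 1e-9 —
a pseudo-counted ratio of normalized means, monotone in the underlying
effect and stable for silent genes. Genes at zero everywhere get p = 1 and
log2FC = 0 by convention. Signatures keep genes passing *strict*
thresholds (log2FC > min_lfc, adjusted p < max_padj), sorted by descending
log2FC with ties broken by gene name, truncated to `top_n`. Two presets
are bundled: subtype identity (top 20, log2FC > 0.25, padj < 0.05) and a
spatial-scoring variant (top 500, log2FC > 0.5, padj < 1e-4) suited to
low-resolution spot data.

The module score of signature G in a cell ranks all genes by decreasing
expression (average ranks for ties — all zero-expression genes share one
bottom tie block), caps ranks at `rank_ceiling` + 1 (default ceiling
1500), and computes the Mann–Whitney statistic
U = Σ_{g∈G} r_g − n(n+1)/2, reporting score = 1 − U/(n · rank_ceiling)
floored at 0. Scores are in [0, 1], exactly invariant to positive
per-cell scaling (hence to library-size differences), and equal 1 when the
signature occupies the top n ranks. The ceiling bounds the penalty from
genes deep in the sparse tail.

## Ligand–receptor communication

The interaction score of pair (L, R) from sender cluster a to receiver b
is (mean_a L + mean_b R)/2 on normalized expression, where a multi-subunit
complex is represented by its limiting (minimum-mean) subunit. A pair is
*tested* only if every ligand subunit is detected (count > 0) in at least
`min_fraction` (default 20%) of sender cells **and** every receptor subunit
likewise in the receiver; requiring both sides matches the behavior of the
standard permutation-based tools, and an `either`-side gate is available as
a switch for the looser reading. Significance comes from shuffling cluster
labels over cells (sizes preserved; optionally within each sample) and
recomputing scores for `n_perm` permutations (default 1000), with the
add-one estimator p = (1 + #{null ≥ obs})/(n_perm + 1), so p ∈
[1/(n_perm+1), 1] and p = 0 is impossible. Results are invariant to the
storage order of cells: the implementation canonicalizes cell order before
drawing permutations.

The chemokine *recruitment score* — sender's mean ligand expression times
the receiver's best mean receptor expression — is an **interpreted
summary** (the underlying readout has no published closed form); it should
be used to rank sender clusters, not as a calibrated statistic, and is
labeled as such in the API documentation.

## Synthetic cohorts

The generator emulates the structure the pipeline is designed to detect:

- **Composition.** Each of K programs has a center on the T-simplex;
  auto-generated centers elevate disjoint blocks of ⌊T/K⌋ cell types by a
  fold of 8 over a uniform baseline (pairwise total-variation separation
  m(f−1)/(T + m(f−1)) ≈ 0.51 for T = 34, K = 6). A sample of program k
  draws its composition from Dirichlet(α · center_k) — α (default 100)
  controls biological sample-to-sample variability — and cell-type counts
  are multinomial given the composition.
- **Expression.** Counts are Gamma–Poisson (negative binomial) with mean
  `baseline_mean` (default 0.5) and size `dispersion` (default 2), typical
  of droplet scRNA-seq; each type's `markers_per_type` (default 20) marker
  genes are elevated `marker_fold`-fold (default 4) in that type, and
  planted ligand/receptor genes are elevated by their stated fold in
  sender/receiver types. Marker blocks are disjoint by construction.
- **CNV labels.** Per-sample label proportions over C clusters come from a
  symmetric Dirichlet with concentration `cnv_diversity`; small values give
  dominant-clone samples (low entropy), large values near-uniform mixtures.
- **Reproducibility.** One global seed feeds counter-based per-sample
  substreams (numpy `SeedSequence` spawn keys), so identical configs are
  byte-identical and extending a cohort never perturbs existing samples.
  `ground_truth_entropy` recomputes a sample's CNV labels from its
  substream and tallies entropy with a plain Counter — an implementation
  path independent of the pipeline's entropy, used as a cross-check.

The default cohort (6 programs × 10 samples, 34 cell types, α = 100,
2,000 cells/sample) is the reference condition for the program-recovery
validation. The generator deliberately omits batch effects, ambient RNA,
doublets and spatial coordinates; passing tests therefore demonstrate
correctness of the statistics and robustness to compositional and count
noise, not robustness to those artifacts in real data.

## Numerical and design notes

- QC thresholds are strict per their conventional wording: cells detecting
  fewer than 200 genes (count > 0) or with a mitochondrial read fraction
  strictly above 0.20 are removed; both criteria are evaluated on the
  input matrix, making the filter idempotent and order-free.
  Mitochondrial genes are recognized by a configurable name prefix
  (default `MT-`).
- Normalization is log1p of library-size scaling to `scale` = 1e4
  counts; all-zero cells are left at zero with a warning. The downstream
  statistics are rank-based precisely so that this simple normalization
  suffices.
- Ties are averaged everywhere ranks appear (Spearman, rank-sum test,
  module score) for internal consistency.
- The permutation-test null calibration in the test suite uses 44 gene
  pairs × 10 disjoint sender/receiver duos (440 combinations) so that the
  null tests are mutually independent — combinations share neither genes
  nor cluster cells — making the binomial reference interval for the
  rejection rate valid.
- Problem sizes in the test and verification workflows (hundreds to a few
  thousand cells per sample, tens of samples, ≤ 1,000 permutations) were
  chosen as the smallest scales at which the asymptotic approximations and
  recovery guarantees hold comfortably; all of them run on a single CPU in
  seconds to a few minutes.

## Known limitations

- No automatic choice of the number of programs k.
- The rank-sum DE p-values are asymptotic; for very small clusters
  (< ~15 cells per side) exact tests would be preferable.
- The LR permutation null shuffles labels globally by default; if cluster
  composition is strongly confounded with sample identity, the
  `within_sample=True` option is the safer null.
- The recruitment score is an interpreted product summary (see above).
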
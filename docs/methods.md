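# Methods

This note describes the statistical procedures implemented in
`m6apattern`, the assumptions behind them, and the design choices made
where the analysis was genuinely open. The package analyses bulk
transcriptomes of rheumatoid arthritis (RA) patients through the lens of
the 20-gene N6-methyladenosine (m6A) regulator panel: a diagnosis model,
consensus modification-pattern clusters, immune profiling of those
clusters, shared differentially expressed genes (DEGs), and a per-sample
m6Ascore used to stratify infliximab response.

## Input model

All stages consume a log2-scale gene-by-sample expression matrix
(normalised array intensities or log2 FPKM). No internal log transform or
normalisation is applied; this is an input contract. Gene identifiers are
matched exactly and case-sensitively. Multi-cohort inputs are merged on
the intersection of their gene sets, optionally z-scoring each gene
within each cohort first (sample sd, ddof 1). That flag is a
deterministic, assumption-light stand-in for cross-platform batch
correction, not a claim that it removes real batch structure; constant
genes map to zero.

## The regulator panel

The bundled panel holds the 20 m6A regulators analysed throughout: eight
writers (METTL3, METTL14, RBM15, RBM15B, WTAP, KIAA1429, CBLL1, ZC3H13),
two erasers (ALKBH5, FTO) and ten readers (YTHDC1, YTHDC2, YTHDF1,
YTHDF2, YTHDF3, HNRNPA2B1, HNRNPC, FMR1, LRPPRC, ELAVL1). It is an
editable CSV data file, as are the HLA and 12-gene immune-checkpoint
panels used in the score-group comparisons.

## Diagnosis model

Samples are split into training and test sets by a stratified split:
the total training count is round(fraction · n) (half up), per-class
counts start at floor(fraction · n_class) and remaining slots go to the
largest fractional remainders. The healthy-control minority of the
training set is balanced by SMOTE — each synthetic control is
x + u(x′ − x) with u ~ U(0, 1) and x′ one of the k = 5 nearest minority
neighbours (Euclidean) — and a 500-tree random forest (sqrt(p) features
per split) is trained on the balanced set. SMOTE runs strictly after the
split: oversampling first would leak interpolants of test-set neighbours
into training, so that ordering is not offered. Test-set performance is
summarised by a ROC curve whose AUC is the tie-corrected Mann–Whitney
concordance; the threshold-sweep polyline integrates to the same value
exactly, and the statistic is invariant under monotone transforms of the
scores.

## Consensus clustering and the choice of k

Modification patterns are found by Monti-style consensus clustering of RA
samples over the z-scored regulator panel: H subsamples of 80% of the
samples (default H = 500), a base clusterer per subsample, and a
consensus matrix M_k(i, j) = co-clustering frequency among subsamples
containing both samples. The default base clusterer is average-linkage
hierarchical clustering on 1 − Pearson correlation; k-means with 10
restarts is selectable. The hierarchical base is preferred for the k
selection diagnostic: with well-separated groups, k-means bisects the
largest cluster almost identically across subsamples, so the consensus
matrix stays near-binary past the true k and the delta-area curve fails
to flatten, whereas the hierarchical base shows the textbook elbow.

For each k, A(k) is the exact area under the empirical CDF of the
upper-triangle consensus entries on [0, 1]; a perfectly binary matrix
with zero-fraction q gives A = q. The relative delta-area is
Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1)) / A(k−1); the chosen k is the
largest k with Δ(k) ≥ 0.1 (configurable), falling back to the per-k
silhouette (computed on the consensus distance 1 − M_k) when nothing
clears the threshold. Final labels cut an average-linkage tree on
1 − M_k and are renumbered by decreasing cluster size.

## Immune profiling (ssGSEA)

Per sample and gene set, the enrichment score is the sum over ranked
positions of a weighted in-set ECDF minus the uniform out-of-set ECDF,
with rank weight rank^0.25 (the conventional ssGSEA exponent). Genes are
ranked by descending expression with ties broken by lexical gene id —
a deterministic choice favoured over midranking inside the running sum
for exact reproducibility. Scores are min-max normalised over the whole
matrix by default. Group comparisons use the two-sided Wilcoxon rank-sum
test (exact when untied, tie-corrected normal approximation without
continuity correction otherwise, so identical groups give p = 1), with a
Kruskal–Wallis omnibus plus all pairwise tests for three or more groups
and Benjamini–Hochberg q-values per test family. The same comparison
operator serves the DAS28 disease-activity checks and the score-group
panel comparisons.

## Differential expression and shared DEGs

Between-cluster DEGs use an empirical-Bayes moderated two-sample t: the
gene-wise pooled variances s² (d = n_a + n_b − 2 df) are modelled as
scaled-F around a prior (d0, s0²) estimated by matching the mean and
variance of log s² (digamma/trigamma identities, trigamma inverted by
Newton iteration); each gene's posterior variance is
(d0·s0² + d·s²)/(d0 + d) and t is referred to d0 + d df (normal when d0
is infinite). When the log-variances have no excess spread the prior
variance is the geometric mean of the observed variances, making
shrinkage towards an identical target an exact no-op. Variances are
floored at 1e-10 and such genes flagged. DEG selection uses raw
p < 0.05 with no fold-change filter (BH q-values are reported for
information only); the shared DEGs are the three-way intersection of the
pairwise contrasts (one-vs-rest is selectable). Over-representation of
the shared DEGs in user-supplied gene sets is the upper-tail
hypergeometric test with BH adjustment.

## The m6Ascore

Shared DEGs are split into positively and negatively correlated sign
groups: each gene's group is the sign of its Pearson correlation with
the first principal axis of the z-scored DEG submatrix, genes with
|r| < 0.3 are dropped, and the orientation is fixed so the positive
group is the larger (tie: the group containing the lexically smallest
gene). The correlate is deliberately label-free and self-consistent;
this is the most consequential interpretation in the package, since the
source analyses do not state what the signature genes were correlated
against. Each sign group is optionally pruned by Boruta against the
cluster label: shadow (permuted) copies of every feature join a random
forest, a feature scores a hit when it out-ranks the best shadow, and a
two-sided binomial test on hit counts at alpha = 0.01 over 100
iterations confirms or rejects; unresolved features are additionally
compared by median importance to the median shadow maximum, and a block
where nothing survives keeps all its genes.

Per block, PC1 loadings are fitted on the centered sample-by-gene
submatrix, oriented so PC1 scores correlate positively with the block's
mean expression (the eigenvector sign is otherwise arbitrary and would
scramble score direction). The score is PC1_pos − PC1_neg with stored
centering; an empty block contributes zero. Samples split into high/low
groups at the median (ties to low). Response analysis reports the
two-sided Wilcoxon rank-sum p of score by response and the ROC AUC of
−score as a predictor of response, so AUC > 0.5 reads "a low score
predicts response" — the direction reported for infliximab.

## Synthetic cohorts

The generator emulates the statistical structure every stage assumes, on
a log2 scale with Gaussian noise (all downstream statistics are rank- or
moment-based, so count-level noise adds nothing the pipeline can see).
Defaults define the study conditions: 300 RA / 100 HC samples, subgroup
proportions 0.234/0.488/0.278 (mirroring the reported 279/581/331 split),
a 1.5-unit RA shift on five designated regulators (FMR1, HNRNPC, LRPPRC,
WTAP, YTHDF3), a 2-unit subgroup shift on disjoint regulator subsets
(6 writers-heavy / 7 eraser-reader / 7 mixed), 500 background genes,
four 25-gene immune signature blocks, unit noise, and a 154-sample
infliximab arm split evenly into responders and non-responders.

Signature-block structure is two-layered. Each block carries a
per-subgroup mean level (steps of immune_effect/2; every block's three
levels are distinct, so each signature gene separates every pair of
subgroups and lands in the three-way DEG intersection; block means rise
A < B < C for the positively loaded blocks and fall for the negative
block, so the adaptive-like subgroup C attains the highest score). A
separate rank-1 response factor loads +1 on all but the last block and
−1 on the last; responders receive −response_score_shift on it, so the
response effect must be recovered through the whole fitting path (sign
groups, Boruta, per-block PC1) rather than being planted on the score
directly. Block counts are deliberately unequal (75 positively vs 25
negatively loaded genes) so the "positive group is larger" orientation
rule resolves the same way in every run. The recorded truth includes the
planted signature activity (block-mean difference plus response factor),
which the fitted score tracks at r ≈ 0.99 under default conditions.

Treated samples are taken round-robin across subgroups and alternate
responder/non-responder, so treatment and response are unconfounded with
subgroup. DAS28-ESR/CRP values are drawn independently of subgroup —
clusters are disease-activity-blind by construction, as the real
clusters were reported to be. Identical (config, seed) reproduces the
matrix bit for bit; different seeds redraw noise only, leaving every
planted mean unchanged.

What the generator does not emulate: platform/probe effects, batch
structure, library-size or count noise, correlated background genes,
gene-gene networks, or missing values. Passing tests therefore
demonstrate the statistical machinery recovers planted structure of the
assumed form, not performance on real cohorts.

## Problem sizes and tolerances

The test suite and the reproduction script run the full pipeline at
300 RA samples with H = 100 consensus subsamples — large enough that
every planted-structure check is far from its decision boundary (the
response Wilcoxon p under default conditions is ~1e-11 against the 0.05
criterion; delta-area at the true k exceeds the 0.1 threshold by ~2.5×)
while a complete run stays under a minute on one CPU. Property tests on
the primitives use exact small-instance oracles (pair-counting AUC up to
12 samples, literal running-sum ssGSEA, hypergeometric enumeration up to
N = 25, a known-prior variance-shrinkage simulation at 2000 genes).

## Known limitations

- The delta-area threshold 0.1 is a heuristic elbow rule; on weakly
  separated data the fallback silhouette rule decides.
- The sign-group correlate (first principal axis of the DEG submatrix)
  is one defensible reading of "positively/negatively correlated
  signature genes"; a per-gene-cluster PC1 variant is not implemented.
- Boruta importance is impurity-based; strongly collinear signature
  blocks dilute per-gene importances, which the keep-all fallback
  mitigates.
- The originally reported cohort-scale numbers (diagnosis AUC 0.83/0.68,
  cluster sizes 279/581/331, 209 shared DEGs) depend on cohorts that are
  not redistributable; the package reproduces the qualitative structure
  at desk scale, not those exact values.
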
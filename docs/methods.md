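# Methods

`regmeth` implements a differential-methylation analysis for
Illumina-style methylation arrays, oriented at studies of regional
identity in epithelium (e.g. gastric antrum / corpus / fundus) and its
dysregulation in pre-neoplastic lesions such as intestinal metaplasia
(IM). This note records the statistical model, the conventions and the
design choices that were genuinely open.

## Value scales

Array methylation is expressed as beta values, the methylated fraction
β ∈ [0, 1] per CpG and sample. Testing is done on M-values,
M = log2(β / (1 − β)), which stabilise the variance near the boundaries;
effect sizes are always reported as **delta beta** (difference of
group-mean β), never back-transformed from the M-scale coefficient.
Betas are clipped to [ε, 1 − ε] before the logit; ε defaults to 1e-3 (a
choice, not a fit — boundary betas otherwise map to ±∞), and the
transform is antisymmetric on the clipped scale.

## Moderated t-statistics

Each CpG is fitted with an ordinary two-group contrast on M-values
(coefficient = difference of group means, pooled residual variance s²_g
with d residual df) or, in paired designs, a one-sample test of the
per-patient differences (equivalent to a blocked two-group fit for
complete balanced pairs, and simpler to validate). Residual variances
are shrunk by empirical Bayes toward a scaled-inverse-chi-square prior
with df d0 and scale s0². The hyperparameters are estimated in closed
form by moment matching on e_g = log s²_g − ψ(d/2) + log(d/2), whose
excess variance beyond the sampling term ψ′(d/2) equals ψ′(d0/2); the
trigamma equation is inverted by Newton iteration. The posterior
variance is s̃²_g = (d0·s0² + d·s²_g)/(d0 + d) and the moderated t is
coef/(u·s̃_g) on d0 + d df. When the excess variance is non-positive,
d0 is set to infinity and s̃² = s0² for every CpG (logged). Setting d0
to 0 via the override recovers the ordinary t exactly — both limits are
exercised in the tests, and the estimator is cross-checked against an
independently coded root-finding oracle at 1e-8.

Multiple testing uses Benjamini–Hochberg throughout. A CpG is called
hypermethylated when Δβ ≥ +0.2 and q < 0.05 (hypomethylated symmetric);
a sensitivity mode (raw p < 0.001, |Δβ| > 0.05) is available for
contrasts with weak expected effects, e.g. differentiation states.
Differential expression reuses the same engine on log2 expression with
|log2FC| > 0.6 and FDR < 0.2 defaults; inter-array quantile
normalisation equalises the column order statistics, ties receiving the
mean of their tied rank means.

## Aggregation rules

A gene is differentially methylated (DM) when ≥ 2 CpGs annotated to it
are DM in the same direction; the minimum drops to 1 for genes on an
explicit exception list (used in the source domain for Wnt-pathway
genes). A promoter is DM when ≥ 1 CpG in TSS1500/TSS200/5'UTR/1stExon
is DM. Directions are counted on disjoint call subsets, so a gene can
appear in both direction tables (information-preserving; the
alternative of suppressing mixed genes was rejected). The per-gene
percentage normalises the direction-specific DM count by all
interrogated CpGs of the gene. Multi-gene CpGs count once per annotated
gene (the manifest semicolon convention). Promoter methylation is the
unweighted mean β over promoter CpGs; promoter–expression integration
uses Pearson correlation across shared samples (the relationship of
interest is linear in the plotted quantities), with constant vectors
flagged undefined rather than silently dropped.

## Enrichment

**Locus overlap.** A CpG (1-based position p) overlaps a BED interval
[start, end) iff start < p ≤ end. Each region set is tested with a
two-sided Fisher's exact test of query vs universe-complement counts;
the two-sided p sums hypergeometric probabilities ≤ (1 + 1e-7) × the
observed table's probability (the convention of the reference exact
test). Odds ratios are the cross-product ad/bc; the Haldane–Anscombe
0.5 correction is applied to the OR only when a cell is zero — never to
the p-value. Effects are reported as log odds ratios in natural log by
default (the base of the published 0.6 threshold is not fixed anywhere
authoritative; `logor_base` switches it), flagged enriched/depleted at
|logOR| > 0.6 with q < 0.05. Degenerate tables (empty margin, e.g.
query = universe) raise rather than returning a silent 0/NaN.

**Feature distribution.** DM CpG counts over the feature-group ×
CGI-relation cross-classification are compared to the universe
composition scaled to the DM total via Pearson residuals
r = (O − E)/√E; Σr² equals the goodness-of-fit chi-square (asserted to
1e-9), and |r| > 1.96 is flagged. Cells absent from the universe get
r = 0.

**CpG sets and GSEA.** Direction-specific CpG sets take called CpGs
with |Δβ| > 0.2 and cap at 2999 members by descending |Δβ| (ties by
smaller p, then lexical id — a deterministic construction; only the cap
itself is inherited from the source analysis). Preranked GSEA uses the
classic weighted Kolmogorov–Smirnov running sum: features ranked by
decreasing moderated t (ties lexical), hits increment by
|score|^w / Σ_set |score|^w with w = 1, misses decrement by 1/(N − K);
ES is the extremum by absolute value (ties resolved toward the positive
extremum; all-zero weight sets fall back to equal hit increments). The
null permutes set membership: n_perm random same-size subsets, shared
across sets of equal size within one call (the null depends only on
K). Nominal p is the same-signed tail with add-one smoothing
(p ≥ 1/(n_perm + 1)); NES divides ES by the mean |permuted ES| of the
same sign; FDR is BH on nominal p (simpler and monotone; the
NES-histogram FDR was deliberately not used). Gene sets outside
15–2000 members are excluded on load; 5000 permutations is the default.

## ExE-hyper-CGI score

Signature intervals are mapped to the closest CpG island on the same
chromosome (gap 0 when overlapping; ties to the lower start, then the
lexically smaller name; intervals on uncovered chromosomes dropped with
a log). The per-sample score is a **two-stage mean** — mean β of the
interrogated CpGs within each island, averaged over islands — not a
pooled CpG mean (islands with many probes would otherwise dominate);
islands without probes are dropped, unweighted. The classification
threshold τ over normal samples is mean + 1.96·sd of the per-sample
scores: "upper 95% limit of the normals" is read as an interval over
samples, since individual samples are classified against it
(`ci_mode="mean"` gives the CI of the mean instead). Group differences
use the Wilcoxon rank-sum test: exact enumeration when both n ≤ 25
without ties, otherwise the normal approximation with tie and 0.5
continuity corrections.

## Sample structure

Ordination is classical metric MDS (principal coordinates) of Euclidean
distances over the 1000 most variable CpGs (ties by id; axis signs
fixed by the largest-magnitude loading so outputs are reproducible).
Cluster selection runs agglomerative hierarchical clustering on beta
profiles — average linkage, Euclidean distance (a common default for
methylation betas; the linkage is a flag) — cuts at k = 2 and returns
the cluster with the highest global mean β. Beta rather than M is
clustered, matching the "high methylation" semantics of the selection.

## Synthetic methylome

The generator produces the study conditions the pipeline is validated
under. Per-CpG baseline means are drawn from a {0.1, 0.9} mixture
(weights 0.5/0.5) and betas from Beta(cμ, c(1 − μ)) with concentration
c = 30, giving the bimodal marginal typical of arrays with a per-group
mean-difference noise scale of ≈ 0.03 at 6 + 6 samples. Planted effects
(default: 5% of CpGs at Δβ = 0.3, shifting the first group) are applied
on the β scale — the scale effects are defined on — with the direction
chosen to keep the target mean in [0.02, 0.98] (hyper at low-baseline,
hypo at high-baseline CpGs). The annotation assigns 1000 genes in
contiguous blocks over five chromosomes, feature groups and CGI
relations from fixed categorical mixes, and ~5% multi-gene CpGs.
Region sets are 2-bp windows centred on CpG positions; the enriched set
samples members with planted CpGs weighted `enrichment_fold` (default
5) times higher, decoys uniformly. Expression couples half of the
planted-promoter genes to mean promoter β with slope −4 log2 units per
β unit plus N(0, 0.25) noise. Paired designs add a per-patient N(0,
0.5) intercept on the M scale. Admixture mixes the pure matrix with a
shared contaminant profile: β_mixed = π·β_pure + (1 − π)·β_cont, so the
observed group delta scales exactly by π; biopsy purities are not
calibrated to any cohort — the π grid 0.4–1.0 used in validation is
illustrative.

What the generator does **not** emulate: Infinium I/II probe-type
chemistry, batch and slide effects, copy-number artifacts, realistic
linkage between neighbouring CpGs, or empirically calibrated purity
distributions. Passing tests therefore demonstrate correctness of the
statistics and plumbing under the stated generative model, not
performance on any particular clinical cohort.

## Problem sizes and determinism

Validation runs use 20,000 CpGs for calibration/recovery checks, 5,000
CpGs × 20 region sets for enrichment recovery, 3,000 CpGs for the
admixture grid and 2,000 CpGs for ExE scoring — sizes at which the
checked quantities are stable across seeds while the whole suite stays
fast. All randomness flows from explicit seeds (one root seed with
named substreams in the simulator and pipeline), and repeated pipeline
runs at a fixed configuration are byte-identical, which is asserted on
file hashes.

## Known limitations

* Regional contrasts pool differentiation states as plain two-group
  comparisons; condition is not modelled as a covariate.
* No mean–variance trend in the variance prior (no trended empirical
  Bayes), no surrogate-variable/batch correction, and no multi-level
  contrasts beyond pairwise.
* Sample-permutation GSEA is out of scope; the membership-permutation
  null is shared across equal-sized sets within a call.
* Upstream array processing (idat parsing, probe filtering, SWAN /
  functional normalisation) is assumed done; the loader intersects
  matrices and annotation on cpg_id.
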
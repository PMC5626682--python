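# Methods

This note documents the statistical models implemented in `intgen`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behavior on real data.

## Differential expression

Gene counts are transformed to log2 CPM,
`log2((c_gs + p) / ((L_s + 2p) / 10^6))` with pseudocount `p = 0.5` and
`L_s` the raw column sum. Effective library size is the raw column total;
no compositional correction (e.g. trimmed-mean scaling) is applied — the
normalization is deliberately the simplest reproducible choice and is
isolated behind `log_cpm` so a different one can be swapped in.

Each gene is fit by ordinary least squares on a design of intercept, a
tumor indicator and dummy-coded covariates (sex, platform). Per-gene
residual variances are shrunk toward the grand mean variance with a prior
of 4 degrees of freedom, `s²_post = (d0·s̄² + df·s²)/(d0 + df)`, and
moderated t-statistics are referred to a t distribution with `df + d0`
degrees of freedom. This is a lighter-weight stand-in for precision-weighted
generalized least squares pipelines: it keeps the variance-moderation idea
(stabilizing small-sample gene variances) without count-level precision
weights. Consequences: at desk-scale simulated depths the moderated fit is
well calibrated (the null-gene false-discovery proportion and permutation
uniformity are tested), but on real data with very low counts the missing
mean–variance weighting would matter.

Direction calls follow the convention that a significant gene (FDR ≤ the
1% threshold) with logFC ≥ 0 is "up"; a logFC of exactly 0 therefore ties
toward "up".

## Differential exon usage

Isoform exon lists are flattened into disjoint counting bins split at every
exon boundary, numbered 5'→3'. Relative usage is
`rel_i = log2(2^{x_i} / Σ_j 2^{x_j})` within each gene, which satisfies
`Σ_j 2^{rel_j} = 1` exactly; single-exon genes are fixed at 0 with a
warning.

The exon-level model is the same moderated linear fit. Per exon, the usage
logFC is the exon's group logFC minus the mean logFC of the gene's other
exons; its variance treats exon estimates as independent,
`Var = v_k + Σ_{j≠k} v_j/(K−1)²`. Gene-level evidence is summarized two
ways: an inverse-variance-weighted F statistic for heterogeneity of exon
logFCs, and the Simes combination `min_k (m·p_(k)/k)` of the per-exon
p-values (using only tested exons as `m`), with BH FDR over the Simes
p-values. Genes with fewer than two exons are skipped and logged.

## Signed co-expression network

Adjacency is `a_ij = ((1 + cor_ij)/2)^β` with β = 12 (the conventional
signed-network default; scale-free fit is not used for automatic
selection), Pearson correlation by default. Topological overlap
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` gives the dissimilarity
for average-linkage clustering. Modules come from a single static cut at
dissimilarity 0.99 with a minimum size of 30; smaller clusters are left
unassigned (label 0). The static cut replaces dynamic hybrid tree cutting:
it is deterministic and directly testable, at the cost of less adaptive
module boundaries — a documented simplification.

The module eigengene is the first right singular vector of the module's
gene-standardized expression block, sign-oriented so its correlation with
the module's average profile is positive, and stored unit-norm. Membership
(kME) is the Spearman correlation of every network gene — not only module
members — with each eigengene; the membership p-value (MMP) is its
two-sided significance via the t approximation with n − 2 df (an exact
permutation p is available for cohorts of ≤ 8 samples; full enumeration
beyond that is disproportionate). Hub genes are ranked by intramodular
connectivity (row sums of the within-module adjacency, diagonal excluded),
ties broken lexicographically.

## Signature projection and the FDR score

Overlaps between a signature and a target set within a universe are tested
with the exact hypergeometric law: one-sided p is `P[X ≥ k]`; two-sided p
sums the probabilities of all tables at most as probable as the observed
one (relative tolerance 1 + 1e−7), matching the convention of common exact
-test implementations. Fold enrichment is observed over expected,
`k·N/(n_sig·n_tgt)` (not an odds ratio — both definitions exist in the
field, and this one is the one asserted in tests). The odds ratio uses the
Haldane 0.5 correction only when a zero cell would make it undefined; the
correction never touches the p-value. BH FDR is computed jointly over all
records of a call. Classification uses strict inequalities: over iff
fold > 2 and FDR < 0.01, under iff fold < 0.6 and FDR < 0.01.

The FDR score maps two-sided records to a signed heat-map value:
`−log2(FDR)` when the odds ratio exceeds 1, `+log2(FDR)` when below 1,
zero whenever FDR > 0.05, absolute value capped at 50 (FDR = 0 scores at
the cap; an odds ratio of exactly 1 has no direction and scores 0).

## DE-ranked axis

The default ordering sorts genes by `sign(logFC)·(−log10 FDR)` ascending,
placing the most significant down-genes at one end and the most
significant up-genes at the other; ties break by logFC then gene id. A
second mode ("paper_literal") orders up-genes ascending by significance
followed by down-genes descending — the two readings of the original
prose conflict, so both are implemented and neither is asserted as
intent. Mark tracks are 0/1 indicators along the axis; the smoothing
curve is the window mean over `[i − 100, i + 100]` (201 genes interior),
truncated — not padded — at the ends, which keeps the curve within [0, 1]
and is the least surprising boundary rule.

## Allele-specific expression

Filters: at least 30 supporting reads; positions (1-based) falling inside
BED mask intervals (0-based half-open) are removed; allele pairs {A,G} and
{T,C} are removed — the reverse complement is excluded because allele
identities are reported on the + strand — which both removes likely RNA
editing and is what lets the empirical null fraction settle near 0.54.

The null reference fraction p0 is the median of per-site pooled fractions
`Σ ref / Σ depth`, estimated separately per group; the median is robust to
a minority of truly imbalanced loci contaminating the null set. The test
is an intercept-only quasi-binomial Wald test against p0: pooled
`p̂ = Σy/Σn` (continuity-corrected to `(Σy+0.5)/(Σn+1)` at 0 or 1),
Pearson dispersion `φ̂ = max(1, (1/(S−1)) Σ (y_s − n_s p̂)²/(n_s p̂(1−p̂)))`
(1 when only one sample), `z = (p̂ − p0)/sqrt(φ̂ p̂(1−p̂)/Σn)`, two-sided
normal p, BH FDR within each group. Only loci observed (after filtering)
in at least one sample of each group are tested; pairing is at the locus
level, not sample level. The "quasi-binomial test" family name does not
pin an estimator; this pooled-Wald operationalization is equivalent to an
intercept-only quasi-binomial fit with an offset null.

Calibration: under a binomial null the test's type-I error at α = 0.05
sits slightly below nominal (the max(1,·) floor on φ̂ is conservative).
Under beta-binomial overdispersion the dispersion estimate needs
replication to stabilize: the calibration simulations use 20 samples per
group — the scale of the motivating cohorts (25 tumors, 22 controls) —
5,000 loci, depth Poisson(60) floored at 30. With few samples (e.g. 5 per
group) the noisy φ̂ leaves residual inflation; this is a real small-sample
limitation of moment-based quasi-likelihood, not an implementation defect.

## Genomic summaries

Burden is the per-sample count of protein-altering somatic variants, with
zero-variant samples counted in the denominator; the reported mean is
rounded to one decimal. Recurrence requires hits in distinct samples
(germline excluded unless requested). Panel coverage marks a sample per
gene via a variant or any gain/loss/cnLOH segment overlapping the gene
(1-based inclusive, ≥ 1 bp overlap), and reports the covered fraction as
an integer percent with round-half-up (22/26 → 85). CNV recurrence tracks
tile chromosomes with 1 Mb bins; a sample counts once per bin per class on
any overlap — the explicit form of what coarse recurrence plots render as
"one line per 20% of the cohort".

## Synthetic data

The generator emulates, mechanistically where it matters:

* gene counts: negative binomial via Gamma–Poisson with Var = μ + αμ²,
  α = 0.1 (typical bulk RNA-seq overdispersion); log2 baseline ~ N(5, 1.5);
  planted log2FCs ~ ±|N(2, 0.25)| on a quarter of genes; module structure
  as a shared per-module Gaussian latent factor (sd 0.8, giving
  within-module correlations around 0.7) with unit loadings; log-normal
  library sizes (σ = 0.3) to exercise CPM normalization;
* exon counts: gene totals negative binomial, multinomial split across
  bins; planted genes double one bin's share in the tumor group with the
  rest renormalized, so total output is matched between groups;
* allele counts: null loci at true fraction 1/2 with each alternate read
  independently dropped with probability `q = 2 − 1/0.54 ≈ 0.148` — the
  reference bias is produced by a process, so the null-fraction estimator
  is tested against a mechanism rather than its own parameter; signal loci
  use their planted fraction; a configurable share of loci carries A/G or
  T/C alleles to exercise the exclusion filter;
* marks and variants: signatures include up-DE genes with probability 0.9
  and background genes with probability 0.1 (the coupling the projection
  statistics are meant to detect), plus a proliferation-like signature
  coupled to planted module 1 the same way; recurrent genes are planted in
  ≥ 2 tumors over a Poisson(10)-per-sample background; segment tables
  plant chr7 gain (~40% of samples) and chr11 loss/cnLOH (~20%).

What passing recovery tests does **not** show: the generator has no GC or
length bias, no batch structure beyond a platform label, no correlated
gene-gene noise outside planted modules, no mapping artifacts beyond the
uniform dropout, and exon bins of implicit equal length. Real-data
behavior at those margins is out of evidence.

All randomness flows from one seed expanded into per-stage substreams by
stable hashing of stage names (CRC32, kept below 2³¹), so a fixed seed
yields a byte-identical bundle and pipeline rerun.

## Problem sizes and numerics

Recovery and calibration suites run at desk scale chosen to make the
statistics decisive rather than marginal: 1,000–2,000 genes, 20 samples
per group, 2 planted 50-gene modules over 300+ background genes, 5,000
ASE loci. Module-recovery scoring uses the no-DE scenario: planted DE
creates a genuine tumor-state correlated component (as in real tumors)
that legitimately dominates clustering, so label-recovery is scored where
module truth is well defined, and the DE scenario is instead exercised
through the projection statistics. Tolerances asserted in tests are stated
inline there; degenerate inputs (constant genes, single-exon genes,
empty tables, zero-variance fractions) are handled by removal-with-warning
or documented conventions rather than NaN propagation.
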
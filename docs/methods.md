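# Methods

## Problem setting

YAP and TAZ (WWTR1) are transcriptional co-activators restrained by the
Hippo kinase cascade; when hyperactive they drive tumor growth and
metastasis through TEAD-family transcription factors. Because their
regulation is mostly post-translational, *YAP1*/*WWTR1* mRNA is a poor
readout of pathway activity; the expression of their target genes is a
better one. `teadsig` implements the analysis chain that (i) derives a
consensus set of activity-responsive genes from several perturbation
experiments, (ii) scores that set per sample, and (iii) asks whether the
score predicts CRISPR-measured dependence on YAP/TAZ/TEADs.

## Signature derivation

Each differential-expression contrast carries an orientation: *activation*
(activity was raised, e.g. a constitutively active YAP mutant) or
*depletion* (activity was lowered, e.g. siRNA against YAP and TAZ).
`orient()` negates log2 fold changes of depletion contrasts once — a flag
guards against double application — so that a positive value always means
"higher with YAP/TAZ activity".

A gene is *regulated* when fold change > 2 and FDR < 0.05, both strict, so
boundary genes are excluded. The consensus rule requires the call in the
anchor contrast **and** in at least `min_support = 2` supporting
contrasts, all in the same oriented direction. Two deliberate edge rules:

* a gene meeting the up rule in the anchor but the down rule in *any*
  support is dropped entirely — a consensus signature should be
  direction-consistent;
* a gene absent from a support table counts as non-supporting, not as
  contradicting (undetected is not evidence of no change).

For synthetic end-to-end runs a documented stand-in DE test is provided:
log2FC of pseudocount-1 TPM group means, Welch's t on log2(1+TPM), and
Benjamini–Hochberg FDR across detected genes. Real-data analyses are
expected to consume externally produced DE tables; the stand-in makes no
claim to count-model realism.

## Enrichment statistics

**Ranking metric.** Signal-to-noise (μ_a − μ_b)/(σ_a + σ_b) with each
class SD floored at max(0.2·|μ|, 1e-8), the conventional desktop-tool
floor; SDs use the n−1 denominator. Ranking ties break lexicographically
by gene symbol so every ordering is deterministic.

**GSEA.** The weighted KS running sum uses hit increments
|r|^w / Σ_hits |r|^w (w = 1 by default) and miss decrements 1/(N − N_h);
the ES is the signed maximum deviation, and the leading edge contains the
hit genes at or before the extremum (at or after it for negative ES). If
all hit metrics are exactly zero the hit weights fall back to equal
weights. Permutation mode follows the group-size rule: phenotype
relabelling when both groups have ≥ 8 samples (the metric is recomputed
and the list re-ranked per permutation), otherwise random genesets of
equal size drawn from the ranked universe, with one shared null pool per
geneset size. NES divides the ES by the mean |permutation ES| of matching
sign; the nominal p compares |ES| against same-sign permutation ES with
add-one smoothing ((b+1)/(m+1)), so p is never zero and the test is
slightly conservative. FDR q follows the pooled positive/negative NES
scheme: the fraction of pooled permutation NES at least as extreme,
divided by the fraction of observed NES at least as extreme, clipped to
[0, 1].

**%-rank.** 100·rank/N with rank 1 the most activity-enriched gene;
bins: top ≤ 15, bottom ≥ 85, mid otherwise, absent when the gene is not
in the list. Bins partition the represented genes.

**GSVA.** Per gene, a kernel CDF estimate across samples:
ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i) with Gaussian bandwidth
h_i = s_i/4; zero-variance genes fall back to h = 1e-8, which degenerates
to a step function. Per sample, genes are ranked by ẑ (descending, symbol
tie-break) and the symmetric rank statistic |N/2 − r|^τ (τ = 1) drives a
KS-like walk over the geneset; with `mx_diff` (the default) the score is
the maximum positive plus the minimum negative deviation. Note that with
the Gaussian kernel the score is exactly invariant under *affine*
transforms of one gene's row (the bandwidth scales with the data) but only
approximately under general monotone transforms; the `ecdf` kernel option
is exactly rank-based and invariant under any strictly increasing
transform. Genes in a geneset but absent from the matrix are dropped from
that set with a log message.

## Dependency prediction

Chronos fitness scores are binarized at ≤ −0.65 (the boundary counts as
dependent); a line is YAP/TAZ-dependent when YAP1 **or** WWTR1 is called,
TEAD-dependent when any of TEAD1–4 is. Lines missing a required score are
excluded with a log message. ROC analysis of GSVA scores against those
labels computes:

* AUC as Mann–Whitney concordance with ties counted 1/2 (rank-sum
  identity), which makes it invariant under strictly increasing score
  transforms;
* a p-value from the DeLong variance of the single-classifier AUC against
  the null AUC = 0.5 (two-sided normal); degenerate zero variance maps to
  p = 0 for AUC ≠ 0.5;
* the Youden-optimal cutoff over midpoints between adjacent distinct
  scores (plus one candidate beyond each extreme), calling positive at
  score ≥ cutoff; J ties resolve to the lowest cutoff. The reported
  sensitivity and specificity are attained at the reported cutoff.

The melanoma lineage filter is a configurable string matched against the
lineage sidecar, not hard-coded, because dependency-portal metadata
vocabularies change across releases.

## Tumor-cohort validation

On log2(1+TPM) values, marker-high/low groups split at mean ± k·SD
(k = 1), inclusive at the boundary. Group comparisons use two-sided
Mann–Whitney with BH correction (the group test is a package choice;
rank-based robustness suits TPM-scale data). Spearman correlations use
average ranks for ties; the permutation p permutes the marker across
samples with (b+1)/(nperm+1) smoothing. Correlation strength bins:
strong r ≥ 0.4, moderate 0.3 ≤ r < 0.4, weak r < 0.3 (the moderate band
is defined half-open so every r has exactly one bin). Constant genes have
undefined r and are flagged: bin weak, p = 1. The similarity matrix is
all-pairs Spearman over all samples, rows and columns sorted by the
anchor-marker correlation; its anchor row reproduces the per-gene marker
correlations exactly. Cohort-level sample QC (e.g. RNA-integrity filters)
is treated as an upstream whitelist input, not recomputed.

## Peak annotation

BED coordinates are 0-based half-open throughout. The promoter window is
TSS ± 1 kb, inclusive of both ends (converted to half-open by extending
the right edge by 1); the TSS is the span start on the + strand and the
last base on the − strand, so the symmetric window is automatically
strand-correct. The priority cascade is Promoter → 5'UTR → 3'UTR → Exon →
Intron → Downstream (3 kb past the 3' end, strand-aware) → Intergenic;
UTR categories participate only when the simplified gene model provides
UTR intervals. Multi-gene overlaps resolve to the smallest |TSS distance|
(midpoint-based), ties to the lexicographically smaller gene id — a
deterministic stand-in for the isoform-level resolution a full annotation
package performs, so real-data counts may differ slightly. Intergenic
peaks record the nearest gene by TSS distance for context but never set a
1 in the gene × dataset peak matrix, whose cells mean "≥ 1 genic or
promoter peak assigned to this gene in this dataset".

## Synthetic data: what it emulates, and what it does not

All generators share a latent per-sample activity factor a_s. Expression
is log2 TPM_gs = baseline_g + β·a_s·(±1 for planted up/down genes) +
N(0, noise_sd), with baseline_g ~ N(4, 2) log2 units, β = 2 (a 4-fold
swing per activity unit), noise_sd = 0.5, and TPM = 2^x − 1 clipped at 0.
Planted-responsive genes have baselines truncated below at 2 log2 units:
a DE analysis can only validate responsive genes expressed above the
pseudocount floor, and untruncated baselines would make "exact recovery"
an ill-posed request of arbitrarily weakly expressed genes.

Defaults mirror the dimensions of the analysis this package
re-implements: 80 planted up / 52 down genes; 4 contrasts (anchor plus 3
supports at inclusion probability 0.8, two of them depletion-oriented);
62 cell lines with 17 TAZ-dependent (2 also YAP-, 9 TEAD1-, 1
TEAD4-dependent); ~300 tumors; 8 peak datasets. Dependent lines draw
a_s ~ N(2, 1) versus N(0, 1) for the rest — a 2-SD activity shift chosen
so that the binormal closed form Φ(2/√2) ≈ 0.92 predicts the achievable
GSVA-score AUC — and Chronos(gene) ~ N(−1.0, 0.15) versus N(−0.1, 0.15),
placing the −0.65 threshold > 2 SD from both means so label errors are
rare. Tumor-cohort correlations are planted through a Gaussian copula
using r = 2·sin(πρ/6), the Pearson value that yields a target Spearman ρ
(naive Pearson planting biases ρ); expression is a monotone lognormal
transform of the latent values, which preserves rank correlations
exactly. Promoter peaks appear at rate 0.9 for targets versus 0.05
background, 200–600 bp wide, centred within the promoter window; the
recovery read-out calls a gene a target when its peak-matrix row sum over
the 8 datasets is ≥ 3, a cutoff fixed in advance from the binomial
separation of Binom(8, 0.9) against Binom(8, 0.05).

What the generators do **not** emulate: count-level noise (negative
binomial overdispersion, library-size effects), batch structure, tumor
purity, isoform complexity, or correlated background genes. Passing tests
therefore demonstrate that the statistical machinery is correct and
well-calibrated under the stated model, not that the biological signature
itself is portable to any particular dataset.

## Problem sizes used in validation

The validation suite runs the oracle comparisons at full prescribed size
(92 genesets; 1000 ROC instances), the GSEA null calibration with 50
genesets × 1000 permutations on a 1000-gene, 8 v 8 matrix, the
dependency experiment over 200 seeded 62-line cohorts of 2000 genes, the
Spearman-planting experiment over 30 seeded 300-tumor cohorts, and the
peak-recovery experiment on one 2000-gene model with 8 datasets. These
sizes give standard errors comfortably below the tolerances being
asserted while keeping a full run in the low minutes on one CPU.

## Known limitations

* The stand-in DE test is not a count-model method; real analyses should
  import DE tables produced by a dedicated tool.
* GSEA FDR q follows the pooled-NES scheme without the desktop tool's
  additional monotonicity post-processing; q values can disagree in the
  tails.
* GSVA with the Gaussian kernel is only affinely rank-stable (see above);
  use `kcdf="ecdf"` for exact rank invariance.
* Peak annotation is single-transcript: no isoform-level resolution, no
  UTR inference when the model lacks UTRs.
* The ROC Youden cutoff assumes "higher score = positive"; a reversed
  marker (e.g. a down-geneset score) yields AUC < 0.5 and an
  uninformative J rather than being auto-flipped — reorientation is the
  caller's decision.
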
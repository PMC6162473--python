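# Methods

`mgtkit` re-implements, at desk scale, the analysis skeleton of a paired
tumour/normal canine mammary-gland-carcinoma (MGC) transcriptome study:
promoter-upstream transcript (PROMPT) quantification, differential
expression with histological-subtype partitioning, correlation-based
multivariate views, cross-species subtype matching, gene–PROMPT
concordance, and qPCR validation statistics. Every stage is driven by a
synthetic-data generator with planted, recoverable structure, so the
whole pipeline is testable without any external download.

## Coordinates and formats

Internally all intervals are 0-based half-open. GTF I/O is 1-based
inclusive (Ensembl dialect); BED I/O is 0-based half-open with the
sample identifier in the BED name column for fragment files. These are
the formats' own conventions; conversions happen only at the I/O
boundary and are covered by round-trip tests.

## PROMPT windows

For each gene the nominal PROMPT window is the 1500 bp immediately
upstream of the transcription start site on the gene's own orientation
(`[tss−1500, tss)` on `+`, `[tss, tss+1500)` in genome coordinates on
`−`), clipped at position 0. Positions overlapping any *other* gene's
transcript span are subtracted; the surviving window may be several
intervals or empty (kept, flagged, effective length 0). The default
exclusion considers other genes' full spans on either strand — upstream
fragment counting is unstranded here, so foreign transcription on either
strand would contaminate the window; `same-strand` and `exons-only`
policies are available. For multi-transcript genes the TSS is the
5′-most transcript start on the gene's strand. The subtraction is
verified against a per-base membership oracle on random annotations and
by a strand-mirroring antisymmetry property.

## Quantification

A fragment counts into a feature when they overlap by ≥ 1 bp (summed
across a multi-interval feature; `min_overlap` is configurable) and
satisfy the strand mode — `same` for gene-level counting of a stranded
library, `ignore` (default) for PROMPT windows. A fragment overlapping k
features increments all k; since windows already exclude foreign gene
spans, double counting is structural only between adjacent windows, and
planted windows in the generator are additionally isolated (below).
FPKM = count × 10⁹ / (length × library size), with the post-exclusion
effective length for PROMPT windows and the per-sample total mapped
fragments as library size.

## Differential expression

log2FC = log2((mean tumour FPKM + ε) / (mean normal FPKM + ε)) with
ε = 0.1 FPKM guarding near-zero denominators. A gene passes when
|log2FC| ≥ 1 (inclusive — "2-fold increases or decreases") **and**
p < 0.01 (strict). No multiple-testing correction is applied by default,
mirroring the raw-threshold convention of the emulated analysis; a
BH-style correction can be layered on the returned p-values.

Three tests operate on log2(FPKM + ε):

- **moderated t (default).** Per-gene pooled variance
  (df = n₁+n₂−2) shrunk toward the across-gene mean pooled variance
  with 4 prior degrees of freedom; t referred to t(prior + residual df).
  Rationale: at 2–3 samples per group a per-gene variance estimate has
  ~2–4 df, and *no* purely per-gene test can call a 4-fold effect at
  p < 0.01 with 90% power under realistic count noise. Pooling variance
  information across genes is how the standard bulk RNA-seq tools
  (Cuffdiff's pooled dispersion, limma, DESeq2) operate; the moderated t
  is the simplest member of that family. The prior df of 4 is a fixed,
  documented constant, not fitted.
- **Welch t**, per gene only.
- **Exact label permutation** on the group-mean difference: full
  enumeration when the labeling count is ≤ C(10,5)=252, else seeded
  Monte-Carlo. Its p cannot go below 2/C(n, n₁) — at 3v3 the floor is
  0.1 — so it is honest but structurally unable to pass the p < 0.01
  gate at subtype sample sizes; use it for 6+ per group (the overall
  8v8 comparison enumerates 12 870 labelings).

Comparisons are unpaired group tests despite the paired design,
matching the per-condition-mean semantics of the emulated pipeline.
Subtype DEG sets are partitioned into all 7 Venn cells per direction;
"subtype-specific" means the exclusive cell.

## Multivariate views

Rows (genes) are z-scored (sample sd, ddof 1); constant rows are
dropped with a warning. Sample clustering uses 1 − Kendall tau-b
(tie-corrected) as dissimilarity with average linkage
(scipy agglomeration; lowest-index pair on ties); the suite checks it
against an O(n³) reference implementation. PCA is the SVD of the
row-z-scored matrix transposed (rows are mean-zero, so samples are
centred in gene space); variance fractions are normalised squared
singular values, cross-checked against scikit-learn. Spearman
correlations use mid-rank ties and equal Pearson-on-ranks by identity.

## Cross-species matching

Subtype signatures are the subtype-exclusive DEGs summarised as mean
log2(FPKM+ε) over that subtype's tumour samples (a fold-change summary
is available — the correlated quantity is a genuinely open choice).
Ortholog pairs are filtered to strict one-to-one (any gene appearing
twice is dropped). Each signature is Spearman-correlated against each
human molecular subtype column on the log scale; with ≤ 8 mapped genes
the two-sided p is an exact permutation p over all orderings, otherwise
the t approximation. Fewer than 3 mapped genes → skipped with a reason.

## Gene–PROMPT concordance

PROMPT-window fold changes are computed on counts scaled per million
mapped fragments per sample (library-size imbalance cancels; verified
by a fragment-duplication oracle) with the same ε. A pair is classified
only when the gene passes its DEG gate and |PROMPT log2FC| ≥ 1;
*positive* = same sign, *negative* = opposite. With one fold change per
gene and one per window, sign concordance **is** the per-pair
correlation notion; the cross-pair trend is the Pearson r of
(gene log2FC, PROMPT log2FC) over positive pairs (negatives are
typically low-coverage artefacts; an all-classified variant is also
reported). Windows averaging fewer than 5 fragments are flagged
`low_count` — a sign from a handful of fragments is noise; the flag is
reported rather than silently filtering.

## qPCR validation

ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the mean normal ΔCt
(or the matched normal in paired mode); relative expression is 2^−ΔΔCt.
Group separation: exact Mann–Whitney U with mid-ranks, U = min(U₁,U₂).
For tie-free data the null distribution of U is enumerated by dynamic
programming — `f(a,b,u) = f(a−1,b,u−b) + f(a,b−1,u)` in exact integer
arithmetic — and the two-sided p is 2·P(U ≤ u), capped at 1 (the null
is symmetric); ties fall back to a seeded label-permutation test. The
DP is cross-checked against full enumeration for all n₁,n₂ ≤ 6 and
against scipy's exact method on random fixtures. The empirical ROC area
is the tie-corrected rank statistic, equal to 1 − U/(n₁n₂) on tie-free
data (min-U convention keeps AUC ≥ 0.5 for both up- and down-regulated
genes); the 95% CI uses the Hanley–McNeil variance. For two groups of
12, U = 27, 31, 34 give p = 0.0083, 0.0173, 0.0284 and AUC = 0.8125,
0.7847, 0.7639 — pure arithmetic, recomputed by `scripts/acceptance.py`.

## Synthetic study generator

The generator emulates the study design: 8 animals in three
histological subtypes (3 complex, 3 ductal, 2 simple), one tumour and
one matched normal per animal; qPCR tables for 12 pairs. Every output
is a pure function of (config, seed) with per-operation seed streams;
reruns are byte-identical.

Key modelling choices, with defaults:

- **Annotation.** 60 genes on 2 chromosomes, lengths 0.8–3 kb, gaps
  0.3–4 kb (so windows frequently collide with neighbour spans,
  exercising exclusion), random strand, 1–2 exons. A divergent "− then
  +" neighbour pair would put both upstream windows into the same gap;
  that configuration alone gets the gap widened by 3 kb so windows stay
  attributable to single genes.
- **Counts.** Negative binomial with mean-dispersion parameterisation
  (dispersion 0.05; 0 degenerates to Poisson for sharp tests). Per-gene
  baselines are log-uniform 50–2000 expected fragments, globally scaled
  to a 300 k-fragment library. Each animal carries a log-normal
  baseline factor (σ = 0.15) shared by its two samples; normal samples
  get extra log-normal spread (σ = 0.15) — normal tissue is the more
  heterogeneous compartment, tumours share a common shift.
- **Planted effects.** 10 overall DEGs (all tumours) and 6 per subtype
  (that subtype's tumours only), signed magnitudes uniform in [2, 4]
  log2 units so every planted effect clears the 2-fold gate by
  construction. The planted genes are jointly rescaled to hold 5% of
  baseline library mass (`planted_mass_fraction`): differential genes
  are a small mass share of real transcriptomes, and keeping the share
  small keeps the FPKM composition bias — up-regulation inflating
  tumour library totals and deflating every measured fold change —
  realistically minor. At desk scale this matters: with ~30% planted
  mass the bias reaches a full log2 unit.
- **PROMPT fragments.** 6 positive and 3 negative planted pairs drawn
  from overall DEGs whose windows are non-empty and overlap no other
  window; active windows emit Poisson fragments at rate 20 per sample
  on the high side and 20/4 on the low side (4-fold), background
  windows at rate 1. Fragments (80 bp, antisense) are placed uniformly
  inside the surviving intervals, so they never cross chromosome
  bounds.
- **Human panel.** 90% of genes get a one-to-one ortholog. One human
  subtype column (TNBC by default) is a noisy monotone transform
  (power 1.3, log-normal σ 0.25) of the matched canine subtype's
  tumour-mean profile; the other columns are independent log-uniform
  profiles.
- **qPCR.** Reference Ct condition-independent in expectation; target
  tumour Ct shifted by −log2(fold); independent Gaussian noise of
  σ = 0.8 cycles on every Ct read-out, so σ = 0 makes the ΔΔCt
  arithmetic exact.

What the generator does **not** emulate: read-level sequence or quality,
alignment ambiguity, GC/length biases, isoform switching, tumour purity
gradients, or batch structure. Passing recovery tests therefore shows
the *pipeline logic* is sound at the study's design and thresholds —
not that the thresholds would behave identically on real libraries.

## Problem sizes and test conditions

Recovery suites run 20 seeds at 100 genes with 10 planted DEGs per
subtype (stable per-seed rates at comfortable runtime): the 3v3
moderated test at the default thresholds attains sensitivity ≥ 0.9 and
false-positive rate ≤ 0.02 in aggregate; all planted PROMPT positives
are recovered with zero adequately-covered background positives; the
planted human subtype tops the correlation ranking in ≥ 19/20 seeds.
The end-to-end determinism check reruns the full pipeline at 50 genes.

## Known limitations

- The moderated t's prior df is fixed, not estimated; with very few
  genes the across-gene variance pool is itself noisy.
- Unpaired testing discards the paired design's power; a paired mode
  would change the effective sample size story at n = 2–3.
- FPKM composition bias is reduced by design in the generator, not
  corrected in the estimator; on data with massive asymmetric
  regulation the fold-change gate shifts accordingly.
- The per-transcript window variant (as opposed to per-gene) is not
  implemented; the generator emits one transcript per gene.
- qPCR efficiency is assumed to be exactly 2 per cycle.
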
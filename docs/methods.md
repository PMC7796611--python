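# Methods

This note documents the statistical procedures implemented in `mscvar`,
the parameter choices that matter, the design of the synthetic cohorts
the test suite runs on, and known limitations.

## Filtering and normalization

Genes are *expressed* when their CPM exceeds 1 in at least
⌈0.10 · n_samples⌉ samples ("more than 1" is read as a strict
inequality, "at least 10%" as a ceiling). Non-expressed genes are
removed before normalization and never re-enter.

Between-sample composition is normalized with the trimmed mean of
M-values (TMM). The implementation follows the published algorithm
exactly: the reference sample is the one whose upper-quartile count
fraction is closest to the cohort mean of that fraction; per sample,
gene-wise log2 ratios M against the reference are kept where finite,
doubly trimmed — the central 40% by M (30% off each tail) and the
central 90% by average log expression A — and averaged with
inverse-asymptotic-binomial-variance weights; factors are rescaled to
geometric mean 1. Factors agree with edgeR's `calcNormFactors` to
machine precision (the test suite verifies 1e-6 against edgeR run
through Rscript). Note that TMM is only *approximately* invariant to
rescaling one sample's counts (≈ 1% movement): the trimmed M statistics
are exactly scale-invariant but the precision weights depend on raw
counts. This matches the reference implementation's behavior.

Downstream expression is log₂(CPM + 1) on TMM-scaled effective library
sizes — log2 with pseudocount 1 being the dominant convention of the
ecosystem this pipeline interoperates with.

Quality control reports, per sample, the median Pearson correlation
with all other samples on log-normalized expression (computed on the
log scale so a handful of very abundant genes cannot dominate);
samples below r = 0.9 are flagged as outliers. ISCT marker expression
(ENG/NT5E/THY1 positive; PTPRC, CD34, CD14, ITGAM, CD79A, CD19,
HLA-DRA, HLA-DRB1 negative) is reported as TPM and within-sample rank
percentile but never used to drop samples — HLA-DR in particular is
legitimately induced by inflammatory stimulation and some expansion
conditions.

## The distance-to-median (DM) variability statistic

CV² (unbiased variance over squared mean of CPM across samples) grows
both with low expression (counting noise) and with gene length. DM
removes both trends nonparametrically:

1. per gene, CV² of CPM across samples;
2. residual of log₁₀ CV² against the rolling median along log₁₀ mean
   CPM;
3. residual of (2) against the rolling median along log₁₀ gene length
   (skipped, with a recorded flag, when lengths are unavailable).

Both residual steps use the same windowing: genes sorted ascending by
the covariate (ties broken by gene ID so results are platform-stable),
partitioned into 50 windows of equal width
w = round((G + 25·49)/50) stepping w − 25, the last window absorbing
the remainder; a gene lying in the overlap of two windows takes the
mean of the two window medians. With fewer genes than windows the
window count drops to ⌊G/2⌋ and the overlap is clamped below the
window width. Residuals are computed on log₁₀ scale, making them
comparable across expression magnitudes and making DM = 1 a tenfold
excess of CV² over the typical gene of the same abundance — the HVG
threshold. Zero-CV² genes are excluded from the median fits and
assigned a sentinel DM one unit below the dataset minimum (log of zero
is undefined; such genes are by construction minimally variable).

The vectorized implementation is verified to 1e-10 against an
independently coded brute-force enumeration, and DM is checked to be
uncorrelated with mean expression (|Spearman ρ| < 0.15) on simulations
with mean-dependent dispersion only. The same (50, 25) windowing is
reused for the length step; both are configurable.

## Sample grouping

PCA is column-centered and unscaled (SVD; component signs canonicalized
by making each loading vector's largest-magnitude entry positive). The
SNN graph over the first 10 PCs gives each sample a neighbor set of its
k = 10 nearest samples (Euclidean, the sample itself included; distance
ties broken by sample order), weighs edges by Jaccard overlap of
neighbor sets, and drops edges below 1/15 — the defaults of the
single-cell toolkit whose clustering contract this reproduces.
Louvain community detection (networkx, Reichardt–Bornholdt
configuration-null modularity) runs at resolution 2 with a required,
logged seed (default 1); labels are size-ordered. Nearest-neighbor
search is exact brute force — cohorts here are hundreds of samples, not
millions of cells.

A property worth knowing: at resolution 2 the modularity objective
legitimately splits communities much larger than k whose SNN is far
from a clique. With k at or above the expected group size (as in the
defaults relative to the planted groups) recovery is exact in the test
conditions.

## Differential expression

Counts are modeled per gene as NB(μ, φ), variance μ + φμ², log link,
offset log(library size × TMM factor), no pseudocounts in fitting.
Dispersion is estimated per gene by maximizing the Cox–Reid adjusted
profile likelihood (profile likelihood minus ½ log det X'WX) on a 12-point,
quadratically refined log grid spanning φ ∈ [1e-4, 10], then shrunk in log
space toward a lowess trend on average log expression with trend
weight 0.25. Tests are likelihood-ratio chi-squares between nested
designs at the shrunk dispersions. This is a deliberate, documented
departure from the empirical-Bayes quasi-likelihood F-test machinery of
edgeR: it preserves the decision contract (NB model, 2-fold, FDR < 0.1)
with a simpler, fully testable statistic. Calibration is verified
empirically: on null cohorts (two identical groups of six) p-values are
uniform (KS < 0.05 per 2000-gene replicate) and type-I error at
α = 0.05 sits near nominal; the realized FDR of DEG calls on
planted-truth cohorts stays within 1.5× nominal.

*CRGs*: design intercept + pair blocks + treatment, 1-df LRT on the
treatment coefficient; called up at log2FC ≥ 1 and BH-FDR < 0.1. The
fold-change gate applies to the fitted coefficient, not raw mean
ratios. *DRGs*: the treatment coefficient is replaced by one response
coefficient per group and tested against the shared-response model
((n_groups − 1)-df LRT); a gene is a DRG when that test passes FDR and
the largest pairwise difference between group response log2FCs is at
least 1. The interaction design is an interpretive choice — "responds
differently among groups" is encoded as a response-by-group
interaction with the pair blocks absorbing all baseline group
differences.

Fitting is IRLS vectorized across genes (one GEMM per iteration for
all normal equations, per-gene convergence tracking), so a
2000-gene × 64-sample cohort's CRG + DRG analysis takes a few seconds.

## Potency signatures

Set algebra: set1 = CRG-only, set2 = CRG ∩ DRG, set3 = DRG-only. The
panel is set2 sorted by descending DM (ties by gene ID), truncated at
100; a smaller set2 is used whole with a warning.

The immunosuppressive score of a treated sample is the sum of
log-normalized expression of seven licensing-associated genes. The
literature labels VEGF, IFNa, GCSF and IL-7 are not canonical HGNC
symbols; the mapping (VEGF→VEGFA, IFNa→IFNA1, GCSF→CSF3, IL-7→IL7,
plus CXCL10, CXCL9, CCL2) is an explicit, logged configuration — IFNA1
in particular is one representative of the IFNA family and can be
overridden. Missing genes contribute zero and are reported.

Quadrant classification runs centered, unscaled PCA on panel-gene
log-normalized expression of the untreated samples only (an option the
analysis fixes; the treated-samples-included variant is a flag at the
library level). Raw PCA quadrants are sign-arbitrary, so PC1/PC2 signs
are flipped to place the centroid of the user-named low-potency
reference group in the third quadrant (both coordinates negative);
every sample then gets a quadrant from its coordinate signs
(1:+/+, 2:−/+, 3:−/−, 4:+/−; a coordinate exactly on an axis — a
probability-zero event — goes to the lower quadrant index) and samples
sharing quadrant 3 are called low-potency. A reference centroid exactly
on an axis raises an error asking for a larger reference set.

The co-culture suppression percentage, 100 × (1 − proliferation with
MSCs / positive control), is provided as a pure function; negative
values (proliferation above control) are returned as-is.

## Ranking and enrichment

Genes are ranked by −log₁₀(max(FDR, 1e-300)) × log2FC (the floor
avoids infinite scores at FDR = 0) or directly by DM, descending, ties
broken by gene ID. Pre-ranked GSEA uses the weighted
Kolmogorov–Smirnov running sum (weight exponent 1 on |score|), gene
sets restricted to ranked genes and size-filtered to [15, 300], a
gene-label permutation null (1000 permutations, seeded; shared across
sets of equal size), sign-matched NES normalization, add-one-corrected
sign-matched empirical p-values, and BH FDR across retained sets. The
desktop tool this emulates defaults to the same scheme for pre-ranked
input.

## Synthetic cohorts

`simulate_cohort` draws NB counts with variance μ + φμ²,
φ = 0.02 + 4/μ. The intercept 0.02 (biological CV ≈ 0.14) reflects
cultured cell-line replicates; it also keeps every planted
variable-gene pattern detectable — CV² of a mean-normalized quantity is
mathematically capped at 4/9 for "one group low, three high" patterns,
so a noisier baseline would make that class of planted HVGs
undetectable by *any* CV-based statistic at the DM > 1 threshold.
Library sizes are log-normal (median 2e6, log-sd 0.35), gene lengths
log-normal (median 2 kb), baseline log2 abundances N(3, 2) with
planted genes drawn N(4, 1.5) so they spread across the expression
range rather than crowding the rolling-median windows.

The default study conditions (`default_paper_like_spec`) are 2000
genes, 4 groups × 8 biological samples, each duplicated into an
untreated/IFNγ pair sharing a per-sample log-normal effect (sd 0.1 on
log2) so the paired design matters. Planted structure:

* 150 HVGs with group-specific baseline shifts of exactly sd 2.0 log2
  per gene (shift vectors are standardized, so "planted variable" is an
  honest per-gene label, not an average);
* 80 CRGs responding 4-fold in every group;
* 60 DRGs responding 4-fold in three groups and not at all in group G0
  (the planted non-responder / low-potency group);
* 40 of the DRGs are also HVGs — the licensing signature. Their
  baseline shifts carry two coherent axes: a potency axis
  (−2.5, 0.3, 0.8, 1.4 per group — the non-responder expresses
  licensing genes lowest at baseline) and a second axis
  (−1.5, −2.0, 1.0, 2.5) with random ±1 gene loadings spreading the
  responder groups, plus per-gene residual shifts (sd 1). The
  two-axis construction encodes the biological premise under test —
  groups occupy a genuinely two-dimensional region of signature space,
  so quadrant membership is meaningful; with a single axis PC1 simply
  points at the outlier group and its PC2 coordinate is noise.
* The seven score genes are signature genes by name; ISCT markers are
  planted constitutively high (positive) or near zero (negative).

Ground-truth "potency" of a group is its planted mean response over
CRG ∪ DRG genes. What these cohorts do **not** emulate: batch/study
effects, gene–gene correlation beyond the planted group structure,
GC/length biases within a sample, outlier samples, isoform-level
effects. Passing recovery tests on them demonstrates that the
implementation recovers what it is designed to recover under its model
assumptions — not that those assumptions hold in any particular real
cohort.

## Numerical and reproducibility choices

Sorting everywhere uses a deterministic secondary key (gene or sample
ID). PCA signs are canonicalized; Louvain and GSEA take explicit seeds;
the CLI fans one global seed out to per-stage seeds by fixed offsets,
so adding a stage never perturbs earlier streams, and `mscvar all`
writes every output with a SHA-256 checksum — identical inputs, config
and seed reproduce identical checksums. IRLS clips the linear predictor
to ±50 and adds a ~1e-10-scaled ridge to the normal equations for rank
safety; the LRT statistic is floored at zero.

Problem sizes in the test and acceptance runs (2000-gene cohorts,
10–20 replicates, 6-replicate null studies) are the package's default
desk-scale study conditions; all scale linearly if enlarged.

## Known limitations

* The NB-GLM LRT is mildly anticonservative when the design has many
  nuisance parameters relative to samples (e.g. 12+ pair blocks on 24
  samples); the calibration guarantees are stated for the tested
  designs at desk scale.
* DM, like any CV-based statistic, has bounded sensitivity to
  variability patterns where a minority of samples under-express a
  gene (the 4/9 ceiling above).
* Quadrant classification is only defined relative to a declared
  low-potency reference group; with a reference whose expression is
  not coherently displaced in panel-gene space the orientation is
  unstable (the axis-centroid error guards the degenerate case).
* The "pre-licensed" state (untreated samples resembling treated ones)
  is surfaced only through the quadrant geometry, not as a separate
  calibrated call.
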
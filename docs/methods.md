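# Methods

## The monitoring problem

Patient-derived renal epithelial cells cultured from urine (hURECs) allow
repeated, non-invasive transcriptomic sampling of the kidney. For a patient
with a lysosomal storage nephropathy (e.g. Fabry disease) under treatment,
the question is whether each follow-up sample's transcriptome looks more
like the patient's own diseased pre-treatment state or like healthy
controls, and how that position moves over the treatment course. This
package implements that analysis as a reusable pipeline: count
preprocessing, disease-signature selection from differential-expression
(DE) results, a per-sample composite similarity score, sample clustering,
and per-phase regression of clinical markers — together with a synthetic
cohort generator used to validate every stage against planted ground truth.

## Similarity score

For gene *g* and sample *s*, CPM values are z-scored across **all** cohort
samples jointly:

    Z_{g,s} = (CPM_{g,s} - mu_g) / sigma_g

with mu_g, sigma_g the per-gene mean and standard deviation of CPM
(sample convention, n-1 denominator; a population-sd option exists). Two
reference profiles are the per-gene mean z over the pre-treatment baseline
replicates and over the healthy controls. The gene-level score of a sample
is

    Score_{g,s} = |Z_{g,s} - Zbar_{g,baseline}| - |Z_{g,s} - Zbar_{g,control}|

and the composite score is the mean of Score_{g,s} over a gene set of size
N (by default the selected disease signature). Positive composites mean the
sample sits nearer the healthy state, negative nearer the diseased state.
By the reverse triangle inequality |Score_{g,s}| <= D_g =
|Zbar_{g,control} - Zbar_{g,baseline}|, so the composite is bounded by the
mean separation Dbar = mean_g D_g: a sample reproducing the control profile
scores exactly +Dbar, the baseline profile -Dbar, and per-gene midpoints 0.
Because z-scoring is invariant to per-gene positive affine maps of the
input, the scores do not depend on gene-wise scaling of CPM.

Interpretation bands are qualitative: scores above +0.1*Dbar are labelled
`control_like`, below -0.1*Dbar `baseline_like`, otherwise `intermediate`.
The 0.1 fraction is a configurable convention, not a clinical threshold.

Two documented consequences of normalising across all samples jointly:
adding a new time point changes every z-score (the affine-invariance
property bounds the effect on score signs), and constant genes
(sigma_g = 0) are excluded from the gene set rather than zero-filled.

## Preprocessing

- **Gene filters.** A gene is retained when it has nonzero counts in
  strictly more than 2 samples and its abundance passes one of two
  readings of a per-sample count rule: `mean` mode (default) keeps genes
  whose mean count per sample exceeds 10; `strict` mode requires more than
  10 counts in every sample. The mean reading retains biologically
  plausible gene numbers on realistic data; both are exposed. The nonzero
  filter is applied first (order configurable). Filtering is idempotent.
- **CPM.** counts / library size * 1e6 with raw library sizes
  (normalisation factors identically 1 — no TMM or median-of-ratios). Every
  CPM column sums to exactly 1e6.
- **log2(CPM+1)** with the pseudocount on the CPM scale.
- **Scaled PCA** for QC: samples are observations, genes are centred and
  scaled to unit variance with the n-1 standard deviation (the R `prcomp`
  scale. = TRUE convention); zero-variance genes are dropped before scaling.

## DE signature

DESeq2-style results tables (baseMean, log2FoldChange, lfcSE, stat, pvalue,
padj) are consumed, not produced: the NB GLM is out of scope. Genes are
classified `up` (log2FC > 1 and padj < 0.05), `down` (log2FC < -1 and
padj < 0.05) or `ns`, all inequalities strict and missing padj counted as
ns. The signature keeps classified genes whose fold-change standard error
is below 0.5 — a reliability filter appropriate to very small designs —
optionally intersected with an external gene list (e.g. pathway-cluster
membership), ordered by |log2FC|. Ranking by the `stat` column produces
.rnk exports for pre-ranked enrichment tools.

For synthetic end-to-end runs an internal Welch-t DE stage operates on
log2(CPM+1): log2FC is the difference of group means on that scale, the
standard error and t statistic are Welch's with Satterthwaite degrees of
freedom, and adjustment is Benjamini-Hochberg. Its +1-pseudocount bias
(estimates shrink toward 0 for low-expressed genes) is documented and
tested rather than corrected.

## Synthetic cohort generator

The generator emulates the longitudinal single-patient design: 3 diseased
baseline replicates, 4 healthy control samples, and 5 single-replicate
treated time points. Each treated sample carries a latent response level
alpha in [0, 1]; its expected expression interpolates per gene between the
diseased baseline state (alpha = 0) and the healthy control state
(alpha = 1) in log2 space:

    mu_{g,s} = control_mean_g * 2^((1 - alpha_s) * log2FC_g)

(a linear-CPM interpolation is available behind `interp_space="linear"`;
both are monotone in alpha, and the linear option makes the score identity
Score_{g,s} = (2*alpha - 1) * D_g exact). Counts are negative binomial with
variance mu + dispersion * mu^2 (dispersion 0 degenerates to Poisson;
`noise="none"` yields deterministic rounded means for noiseless checks),
scaled by per-sample lognormal library-size factors.

Defaults, chosen once as a realistic bulk RNA-seq scenario:

| parameter | default | rationale |
|---|---|---|
| n_genes | 20,000 | transcriptome scale; the signature must be a small mass fraction (see bias note below) |
| n_up / n_down | 551 / 347 | planted signature size at the scale the analysis targets |
| effect range | [1, 4] log2 units | bulk of a DE signature; extremes beyond 10 occur but are rare |
| control-state means | lognormal(meanlog 4, sdlog 1.2), rescaled to the library size | ~98% of genes pass the default filters |
| library size | 5e6 mean, lognormal +/-20% | modest sequencing depth; CPM != raw counts in tests |
| dispersion | 0.1 | typical bulk RNA-seq overdispersion |
| alpha trajectory | t1 0.10, t2 0.80, t3 0.50, t4 0.05, t5 0.60 | minimal early change, strong mid-course response, relapse, renewed response after the therapy switch |

The clinical series is piecewise-linear eGFR (plus optional uPCR) with
Gaussian noise: default 42 ml/min/1.73m^2 at month 0 falling to 30 at
month 13 through three phases (pre-treatment slope -2.0, chaperone -0.5,
ERT -1.5 per month, breaks at months 3 and 12), so the pre-treatment
decline is steeper than the on-chaperone decline.

**Compositional bias of CPM.** Because the diseased state up-regulates more
transcript mass than it loses, diseased samples have larger expected
library mass; dividing by the library makes every CPM-scale fold change
shift by -log2(mass ratio). At the default scale the shift is ~0.2 log2
units; at small gene universes (where the signature dominates the library)
it can exceed 1 and systematically biases threshold classification — one
reason real pipelines use median-of-ratios normalisation for DE. The
Welch-t validation therefore runs at transcriptome scale, and the residual
shift explains a modest excess of down-calls among null genes. The
similarity score is much less sensitive: it compares each sample with both
references on the same z-scale, and composite monotonicity in alpha is
preserved.

What the generator does **not** emulate: batch effects, cell-type
composition drift between cultures, sex-specific mosaicism, gene-gene
correlation, and count-level artefacts of alignment/quantification.
Passing recovery tests therefore show the pipeline's statistical machinery
is correct under the assumed NB model, not that real hUREC cultures are
free of these confounders.

## Clustering and slope regression

Sample dissimilarity is Euclidean distance (1 - Pearson available) on the
z-scored signature-gene matrix by default; agglomeration is strictly
complete linkage (cluster distance = largest pairwise distance), which
guarantees non-decreasing merge heights. Dendrograms serialise to Newick
with branch lengths from merge heights. Flat clusters come from cutting
the merge sequence.

Clinical markers are fitted by ordinary least squares independently within
each treatment phase (break points are given, not estimated): slope,
intercept, analytic slope standard error and a 95% CI from the t
distribution with n-2 df. Two-point phases yield an exact interpolating
line; their zero standard error and collapsed CI are flagged `degenerate`
rather than hidden. Slope comparisons across phases use the independent-fit
approximation se(diff) = sqrt(se1^2 + se2^2).

## Numerical conventions and edge cases

- Standard deviations use the n-1 denominator throughout (R convention).
- Zero-variance genes: dropped (PCA scaling and z-scores undefined),
  with counts logged.
- Welch t with two identical groups (0/0): defined as t = 0, p = 1; a
  nonzero mean difference with zero variance is maximally significant.
- Filters and classification use strict inequalities exactly as stated.
- Empty filter results return an explicit empty matrix with a warning;
  an empty signature raises an error advising threshold relaxation.
- Clustering tie-breaks follow the linkage implementation's
  lowest-index-first order; validation instances use continuous data where
  ties have probability zero.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical matrices.

## Validation problem sizes

The test suite exercises small cohorts (hundreds of genes) for unit checks
and the full default scale (20,000 genes, 12 samples, 20 seeded replicates)
for recovery properties; brute-force oracles (filter rule enumeration,
literal BH step-up, O(n^3) agglomeration, closed-form OLS) are implemented
independently in the tests and compared exactly.
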
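# rnamonitor

Longitudinal transcriptomic treatment monitoring for patient-derived renal
epithelial cells.

Renal tubular epithelial cells cultured from urine (hURECs) make it
possible to re-sample a patient's kidney transcriptome non-invasively over
a treatment course. Given bulk RNA-seq counts for pre-treatment (diseased
baseline) replicates, healthy controls, and single-replicate treated time
points, this package answers: *how close is each treated sample to the
healthy versus the diseased transcriptional state, and how does that
position move across treatment phases?* It targets monitoring scenarios
such as Fabry nephropathy under chaperone therapy and enzyme replacement
therapy (ERT).

## The score

CPM expression is z-scored per gene across all samples,
`Z_gs = (CPM_gs − μ_g)/σ_g`. With `Z̄_g,baseline` and `Z̄_g,control` the mean
z-profiles of the two reference groups, each treated sample *s* gets

```
Score_gs       = |Z_gs − Z̄_g,baseline| − |Z_gs − Z̄_g,control|
CompositeScore_s = (1/N) Σ_g Score_gs        (over a signature of N genes)
```

Positive composites mean the sample resembles the healthy controls,
negative the diseased baseline; the score is bounded by ±D̄, the mean
per-gene separation of the two references. The signature is selected from
DESeq2-style DE results (padj < 0.05, |log2FC| > 1, lfcSE < 0.5). Around
the score sit the supporting stages: count filters, CPM and log2(CPM+1),
scaled PCA, complete-linkage sample clustering, per-phase OLS of clinical
markers (eGFR, uPCR), and a negative-binomial synthetic-cohort generator
with planted ground truth.

## Worked example

```python
import scipy.stats
from rnamonitor import (simulate_cohort, filter_genes, compute_cpm,
                        SimilarityScorer)

cm, truth = simulate_cohort(seed=1)          # 20,000 genes x 12 samples
cpm = compute_cpm(filter_genes(cm))
genes = [g for g in truth.signature_genes() if g in cpm.values.index]
scorer = SimilarityScorer(gene_set=genes).fit(
    cpm.values.T, cm.sample_meta.loc[list(cpm.values.columns), "group"])
res = scorer.score_samples(cm.samples_in_group("treated"))
print(res.composite.round(3))
print("Dbar =", round(res.mean_separation, 3))
alphas = [truth.alphas[s] for s in res.composite.index]
print("Spearman(alpha, composite) =",
      scipy.stats.spearmanr(alphas, res.composite).statistic)
```

Output:

```
t1   -1.141
t2    1.084
t3    0.114
t4   -1.303
t5    0.397
dtype: float64
Dbar = 1.895
Spearman(alpha, composite) = 0.9999999999999999
```

The five treated time points follow the planted response trajectory
(α = 0.10, 0.80, 0.50, 0.05, 0.60): near-baseline at t1, a strong shift
toward the healthy state at t2 (+1.08 of a maximum +1.89), partial recovery
at t3, relapse at t4, renewed improvement after the switch to ERT at t5 —
and the composite ranks the time points exactly as the latent response
levels do.

The same pipeline is scriptable from the shell:

```
rnamonitor simulate --seed 1 --outdir cohort/
rnamonitor preprocess --counts cohort/counts.tsv --meta cohort/metadata.tsv --out prep/
rnamonitor score --counts cohort/counts.tsv --meta cohort/metadata.tsv \
    --signature cohort/truth_signature.tsv --out scored/
rnamonitor trajectory slopes --input cohort/clinical.tsv --out slopes/
```

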
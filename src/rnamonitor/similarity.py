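"""Gene-expression similarity scores for longitudinal treatment monitoring.

For each gene g, CPM values are z-scored across all samples jointly
(Z_{g,s} = (CPM_{g,s} - mu_g) / sigma_g). Two reference profiles are the
per-gene mean z over the diseased pre-treatment baseline replicates and over
the healthy control samples. A treated sample s is scored per gene as

    Score_{g,s} = |Z_{g,s} - Zbar_{g,baseline}| - |Z_{g,s} - Zbar_{g,control}|

so positive scores mean the gene sits nearer the healthy state and negative
scores nearer the diseased state; the composite score is the mean over a
chosen gene set (typically the disease signature). By the reverse triangle
inequality |Score_{g,s}| <= D_g = |Zbar_{g,control} - Zbar_{g,baseline}|, so
the composite lives in [-Dbar, +Dbar] with Dbar the mean per-gene separation:
a sample matching the control profile scores +Dbar, one matching the baseline
profile -Dbar, and equidistant profiles score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix
from .de import SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ZScoreMatrix",
    "ReferenceProfiles",
    "SimilarityResult",
    "SimilarityScorer",
    "zscore_normalize",
    "reference_profiles",
    "gene_scores",
    "composite_scores",
    "interpret_score",
]


@dataclass
class ZScoreMatrix:
    """Per-gene z-scored expression with the (mu, sigma) normalisation stats."""

    z: pd.DataFrame  # genes x samples
    norm_stats: pd.DataFrame  # columns mu, sigma
    source_transform: str = "cpm"


@dataclass
class ReferenceProfiles:
    """Mean z-profiles of the two reference states and their separation."""

    z_baseline: pd.Series
    z_control: pd.Series
    baseline_ids: list[str]
    control_ids: list[str]

    @property
    def separation(self) -> pd.Series:
        """Per-gene separation D_g = |Zbar_control - Zbar_baseline|."""
        return (self.z_control - self.z_baseline).abs()

    @property
    def mean_separation(self) -> float:
        return float(self.separation.mean())


@dataclass
class SimilarityResult:
    gene_scores: pd.DataFrame  # genes x scored samples
    composite: pd.Series  # per scored sample
    interpretation: pd.Series  # control_like / intermediate / baseline_like
    mean_separation: float
    n_genes: int


def zscore_normalize(em: ExpressionMatrix, gene_set: list[str] | None = None,
                     ddof: int = 1) -> ZScoreMatrix:
    """Z-score CPM values per gene across all samples.

    Uses the sample (n-1) standard deviation by default (``ddof=0`` for the
    population convention). Genes with zero variance are removed and counted.
    """
    em.require_transform("cpm")
    vals = em.values
    if gene_set is not None:
        missing = set(gene_set) - set(vals.index)
        if missing:
            raise KeyError(f"gene(s) not in expression matrix: {sorted(missing)[:5]}")
        vals = vals.loc[list(gene_set)]
    if vals.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=ddof)
    keep = sigma > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d constant genes (sigma = 0) before z-scoring",
                    n_dropped)
    vals = vals.loc[keep]
    z = vals.sub(mu[keep], axis=0).div(sigma[keep], axis=0)
    stats = pd.DataFrame({"mu": mu[keep], "sigma": sigma[keep]})
    return ZScoreMatrix(z=z, norm_stats=stats, source_transform=em.transform)


def reference_profiles(z: ZScoreMatrix, meta: pd.DataFrame) -> ReferenceProfiles:
    """Per-gene mean z over the baseline and control sample groups."""
    groups = meta.loc[list(z.z.columns), "group"]
    baseline_ids = list(groups.index[groups == "baseline"])
    control_ids = list(groups.index[groups == "control"])
    if not baseline_ids or not control_ids:
        raise ValueError(
            f"need >=1 baseline and >=1 control sample "
            f"(got {len(baseline_ids)} and {len(control_ids)})"
        )
    return ReferenceProfiles(
        z_baseline=z.z[baseline_ids].mean(axis=1),
        z_control=z.z[control_ids].mean(axis=1),
        baseline_ids=baseline_ids,
        control_ids=control_ids,
    )


def gene_scores(z: ZScoreMatrix, refs: ReferenceProfiles,
                scored_samples: list[str]) -> pd.DataFrame:
    """Per-gene similarity scores for the given samples.

    Score_{g,s} = |Z_{g,s} - Zbar_baseline| - |Z_{g,s} - Zbar_control|;
    positive = nearer the healthy control state.
    """
    unknown = set(scored_samples) - set(z.z.columns)
    if unknown:
        raise KeyError(f"unknown sample id(s): {sorted(unknown)}")
    zs = z.z[list(scored_samples)]
    d_base = zs.sub(refs.z_baseline, axis=0).abs()
    d_ctrl = zs.sub(refs.z_control, axis=0).abs()
    return d_base - d_ctrl


def composite_scores(scores: pd.DataFrame,
                     gene_set: SignatureSet | list[str] | None = None) -> pd.Series:
    """Arithmetic mean of gene-level scores over the gene set, per sample."""
    genes = None
    if isinstance(gene_set, SignatureSet):
        genes = gene_set.gene_ids
    elif gene_set is not None:
        genes = list(gene_set)
    if genes is not None:
        if not genes:
            raise ValueError("empty gene set")
        missing = set(genes) - set(scores.index)
        if missing:
            raise KeyError(f"gene(s) missing from score matrix: {sorted(missing)[:5]}")
        scores = scores.loc[genes]
    if scores.empty:
        raise ValueError("empty gene set")
    return scores.mean(axis=0)


def interpret_score(composite: pd.Series | float, refs: ReferenceProfiles,
                    epsilon_frac: float = 0.1):
    """Band composite scores into control_like / intermediate / baseline_like.

    The band half-width is epsilon_frac times the mean per-gene separation
    Dbar; scores above +eps are control-like (healthy-shifted), below -eps
    baseline-like (persistently diseased), otherwise intermediate.
    """
    dbar = refs.mean_separation
    if dbar <= 0:
        raise ValueError("degenerate references: mean separation is 0")
    eps = epsilon_frac * dbar
    scalar = np.isscalar(composite)
    comp = pd.Series([composite]) if scalar else composite
    labels = pd.Series(
        np.where(comp > eps, "control_like",
                 np.where(comp < -eps, "baseline_like", "intermediate")),
        index=comp.index,
    )
    return labels.iloc[0] if scalar else labels


class SimilarityScorer(BaseEstimator):
    """Estimator wrapper around the similarity-score pipeline.

    ``fit(X, y)`` takes a samples x genes CPM DataFrame (all cohort samples:
    the z-normalisation is computed across every sample jointly) and group
    labels y in {baseline, control, treated}. ``transform`` / ``score_samples``
    then return gene-level and composite scores for any subset of the fitted
    samples.

    Parameters
    ----------
    gene_set : optional list of gene ids to score (default: all retained genes)
    ddof : standard-deviation convention (1 = sample, R-style; 0 = population)
    epsilon_frac : interpretation band half-width as a fraction of Dbar
    """

    def __init__(self, gene_set=None, ddof: int = 1, epsilon_frac: float = 0.1):
        self.gene_set = gene_set
        self.ddof = ddof
        self.epsilon_frac = epsilon_frac

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        meta = pd.DataFrame({"group": np.asarray(y)}, index=X.index)
        genes = None
        if self.gene_set is not None:
            genes = (self.gene_set.gene_ids
                     if isinstance(self.gene_set, SignatureSet) else list(self.gene_set))
        em = ExpressionMatrix(X.T, "cpm", sample_meta=meta)
        self.z_ = zscore_normalize(em, gene_set=genes, ddof=self.ddof)
        self.refs_ = reference_profiles(self.z_, meta)
        self.mean_separation_ = self.refs_.mean_separation
        self.genes_ = list(self.z_.z.index)
        return self

    def transform(self, sample_ids=None) -> pd.DataFrame:
        """Gene-level scores (samples x genes) for fitted samples."""
        ids = list(sample_ids) if sample_ids is not None else list(self.z_.z.columns)
        return gene_scores(self.z_, self.refs_, ids).T

    def score_samples(self, sample_ids=None) -> SimilarityResult:
        ids = list(sample_ids) if sample_ids is not None else list(self.z_.z.columns)
        gs = gene_scores(self.z_, self.refs_, ids)
        comp = composite_scores(gs)
        return SimilarityResult(
            gene_scores=gs,
            composite=comp,
            interpretation=interpret_score(comp, self.refs_, self.epsilon_frac),
            mean_separation=self.mean_separation_,
            n_genes=len(self.genes_),
        )
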
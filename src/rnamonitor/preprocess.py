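"""Count preprocessing: gene-retention filters, CPM, log2(CPM+1), scaled PCA.

Estimator classes follow the scikit-learn transformer protocol and operate on
samples x genes DataFrames; the module-level functions are thin wrappers that
work directly on the gene x sample :class:`~rnamonitor.containers.CountMatrix`
and :class:`~rnamonitor.containers.ExpressionMatrix` containers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .containers import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

CPM_SCALE = 1e6


class GeneFilter(BaseEstimator, TransformerMixin):
    """Retain genes expressed robustly across samples.

    A gene is kept when it has nonzero counts in strictly more than
    ``min_nonzero_samples`` samples AND passes the abundance rule:
    ``mode="mean"`` requires mean count per sample strictly above
    ``min_mean_count``; ``mode="strict"`` requires every sample's count
    strictly above it. Both filters guard against genes seen only in a few
    samples of a heterogeneous primary-cell culture.
    """

    def __init__(self, min_nonzero_samples: int = 2, min_mean_count: float = 10.0,
                 mode: str = "mean"):
        self.min_nonzero_samples = min_nonzero_samples
        self.min_mean_count = min_mean_count
        self.mode = mode

    def fit(self, X: pd.DataFrame, y=None):
        if self.min_nonzero_samples < 0 or self.min_mean_count < 0:
            raise ValueError("thresholds must be >= 0")
        if self.mode not in ("mean", "strict"):
            raise ValueError(f"mode must be 'mean' or 'strict', got {self.mode!r}")
        X = pd.DataFrame(X)
        nonzero = (X > 0).sum(axis=0)
        keep = nonzero > self.min_nonzero_samples
        if self.mode == "mean":
            keep &= X.mean(axis=0) > self.min_mean_count
        else:
            keep &= (X > self.min_mean_count).all(axis=0)
        self.support_ = keep.to_numpy()
        self.retained_genes_ = list(X.columns[keep])
        self.n_removed_ = int((~keep).sum())
        logger.info(
            "gene filter (%s mode): retained %d / %d genes (%d removed)",
            self.mode, len(self.retained_genes_), X.shape[1], self.n_removed_,
        )
        if not self.retained_genes_:
            logger.warning("gene filter removed every gene")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).loc[:, self.retained_genes_]


class CPMNormalizer(BaseEstimator, TransformerMixin):
    """Counts-per-million scaling: each sample row is divided by its library
    size (row sum of raw counts) and multiplied by 1e6, so every sample sums
    to exactly one million."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        lib = X.sum(axis=1)
        zero = lib[lib <= 0]
        if len(zero):
            raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
        return X.div(lib, axis=0) * CPM_SCALE


class Log2CPMTransformer(BaseEstimator, TransformerMixin):
    """log2(CPM + 1): monotone variance-stabilising transform mapping 0 -> 0."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if (X.to_numpy() < 0).any():
            raise ValueError("CPM values must be non-negative")
        return np.log2(X + 1.0)


class ScaledPCA(BaseEstimator, TransformerMixin):
    """PCA on unit-variance-scaled expression, mirroring R's prcomp(scale.=TRUE).

    Samples are observations and genes variables; each gene is centred and
    divided by its sample (n-1) standard deviation before the decomposition.
    Zero-variance genes are removed (scaling is undefined for them) and
    counted in ``n_zero_variance_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        n_samples, _ = X.shape
        if n_samples < 2:
            raise ValueError("PCA requires at least 2 samples")
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        self.n_zero_variance_ = int((~keep).sum())
        if self.n_zero_variance_:
            logger.info("dropping %d zero-variance genes before scaling",
                        self.n_zero_variance_)
        Xk = X.loc[:, keep]
        self.genes_ = list(Xk.columns)
        max_rank = min(n_samples - 1, Xk.shape[1])
        k = self.n_components if self.n_components is not None else max_rank
        if k > max_rank:
            raise ValueError(
                f"n_components={k} exceeds min(n_samples - 1, n_genes) = {max_rank}"
            )
        self.mean_ = Xk.mean(axis=0)
        self.scale_ = Xk.std(axis=0, ddof=1)
        Z = (Xk - self.mean_) / self.scale_
        self._pca = PCA(n_components=k)
        self._pca.fit(Z.to_numpy())
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.components_ = self._pca.components_
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).loc[:, self.genes_]
        Z = (X - self.mean_) / self.scale_
        scores = self._pca.transform(Z.to_numpy())
        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=X.index, columns=cols)

    def inverse_transform(self, scores) -> np.ndarray:
        """Back to the scaled-gene space (not the raw expression space)."""
        return self._pca.inverse_transform(np.asarray(scores))


# ---------------------------------------------------------------------------
# Container-level wrappers


def filter_genes(cm: CountMatrix, min_nonzero_samples: int = 2,
                 min_mean_count: float = 10.0, mode: str = "mean") -> CountMatrix:
    """Apply the gene-retention filters to a CountMatrix (genes x samples)."""
    f = GeneFilter(min_nonzero_samples, min_mean_count, mode).fit(cm.counts.T)
    return CountMatrix(cm.counts.loc[f.retained_genes_], cm.sample_meta)


def compute_cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million from raw library sizes (normalisation factors = 1)."""
    cpm = CPMNormalizer().fit_transform(cm.counts.T).T
    return ExpressionMatrix(cpm, "cpm", sample_meta=cm.sample_meta)


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) of a CPM matrix."""
    em.require_transform("cpm")
    vals = Log2CPMTransformer().fit_transform(em.values.T).T
    return ExpressionMatrix(vals, "log2cpm1", sample_meta=em.sample_meta)


def pca(em: ExpressionMatrix, n_components: int | None = None):
    """Scaled PCA on a log2(CPM+1) matrix.

    Returns (scores, explained_variance_ratio): scores is a samples x PCs
    DataFrame; the ratio entries are non-increasing and sum to <= 1.
    """
    em.require_transform("log2cpm1")
    est = ScaledPCA(n_components=n_components).fit(em.values.T)
    return est.transform(em.values.T), est.explained_variance_ratio_
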
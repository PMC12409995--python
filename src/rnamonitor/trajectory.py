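"""Longitudinal structure: sample clustering and clinical slope regression.

Complete-linkage hierarchical clustering groups samples by expression so
treated time points can be read against the diseased-baseline and
healthy-control clusters; per-phase ordinary least squares quantifies the
rate of clinical decline (eGFR in ml/min/1.73m^2 per month) across the
pre-treatment, chaperone and ERT phases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTree",
    "PhaseFit",
    "CompleteLinkageTree",
    "PhaseSlopeRegressor",
    "hcluster_samples",
    "cut_tree",
    "to_newick",
    "fit_phase_regressions",
    "compare_slopes",
]


@dataclass
class LinkageTree:
    """Agglomeration history in scipy linkage-matrix form plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class PhaseFit:
    """OLS fit of a clinical marker within one treatment phase."""

    phase: str
    slope: float
    intercept: float
    slope_se: float
    ci95: tuple[float, float]
    n: int
    degenerate: bool = False  # exact 2-point fit: se = 0, CI collapses


class CompleteLinkageTree(BaseEstimator):
    """Complete-linkage agglomerative clustering of samples.

    ``fit(X)`` takes a samples x features DataFrame; pairwise dissimilarities
    use ``metric`` ("euclidean" or "correlation" = 1 - Pearson) and clusters
    merge at the largest pairwise distance between their members.
    """

    def __init__(self, metric: str = "euclidean"):
        self.metric = metric

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("clustering needs at least 2 samples")
        if X.isna().to_numpy().any():
            raise ValueError("NaN in input matrix")
        if self.metric not in ("euclidean", "correlation"):
            raise ValueError(f"unsupported metric {self.metric!r}")
        d = ssd.pdist(X.to_numpy(), metric=self.metric)
        self.linkage_ = sch.linkage(d, method="complete")
        self.tree_ = LinkageTree(linkage=self.linkage_, leaves=list(X.index))
        return self

    def cut(self, k: int) -> pd.Series:
        return cut_tree(self.tree_, k)


def hcluster_samples(values: pd.DataFrame, metric: str = "euclidean") -> LinkageTree:
    """Cluster the columns (samples) of a genes x samples matrix."""
    est = CompleteLinkageTree(metric=metric).fit(values.T)
    return est.tree_


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    """Flat cluster labels from cutting the tree into k clusters."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = sch.cut_tree(tree.linkage, n_clusters=k).ravel()
    return pd.Series(labels, index=tree.leaves, name="cluster")


def to_newick(tree: LinkageTree) -> str:
    """Serialise the dendrogram as Newick, branch lengths from merge heights."""
    root = sch.to_tree(tree.linkage)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.leaves[node.id]}:{length:g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({recurse(root.left, root.dist)},{recurse(root.right, root.dist)});"


class PhaseSlopeRegressor(BaseEstimator):
    """Independent per-phase OLS fits of a clinical marker against time.

    Slopes are in marker units per month; 95% confidence intervals use the
    t distribution with n-2 degrees of freedom, mirroring standard lm
    behaviour. Two-point phases give an exact interpolating line with zero
    standard error; these are flagged ``degenerate``.
    """

    def __init__(self, marker: str = "egfr"):
        self.marker = marker

    def fit(self, clinical: pd.DataFrame, y=None):
        if self.marker not in clinical.columns:
            raise ValueError(f"marker {self.marker!r} not in clinical series")
        df = clinical.dropna(subset=[self.marker])
        fits = []
        for phase in pd.unique(df["phase"]):
            sub = df[df["phase"] == phase]
            if len(sub) < 2:
                warnings.warn(f"phase {phase!r} has <2 points; skipped")
                continue
            fits.append(self._fit_phase(phase, sub["time_months"].to_numpy(),
                                        sub[self.marker].to_numpy()))
        self.fits_ = fits
        return self

    @staticmethod
    def _fit_phase(phase: str, t: np.ndarray, y: np.ndarray) -> PhaseFit:
        n = len(t)
        tbar, ybar = t.mean(), y.mean()
        sxx = float(((t - tbar) ** 2).sum())
        if sxx == 0:
            raise ValueError(f"phase {phase!r}: all time points identical")
        slope = float(((t - tbar) * (y - ybar)).sum() / sxx)
        intercept = float(ybar - slope * tbar)
        resid = y - (intercept + slope * t)
        rss = float((resid**2).sum())
        if n > 2:
            s2 = rss / (n - 2)
            se = float(np.sqrt(s2 / sxx))
            tcrit = float(scipy.stats.t.ppf(0.975, n - 2))
            ci = (slope - tcrit * se, slope + tcrit * se)
            degenerate = False
        else:
            se = 0.0
            ci = (slope, slope)
            degenerate = True
        return PhaseFit(phase=phase, slope=slope, intercept=intercept,
                        slope_se=se, ci95=ci, n=n, degenerate=degenerate)


def fit_phase_regressions(clinical: pd.DataFrame, marker: str = "egfr") -> list[PhaseFit]:
    """Per-phase OLS of a clinical marker (egfr or upcr) against time."""
    if marker not in ("egfr", "upcr"):
        raise ValueError(f"marker must be 'egfr' or 'upcr', got {marker!r}")
    return PhaseSlopeRegressor(marker=marker).fit(clinical).fits_


def compare_slopes(fits: list[PhaseFit]) -> dict:
    """Tabulate per-phase slopes, pairwise differences, and their ordering.

    Differences use the independent-fit approximation
    se(diff) = sqrt(se1^2 + se2^2). The ordering string lists phases from
    steepest decline (most negative slope) to shallowest.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 phase fits to compare")
    table = pd.DataFrame(
        {
            "phase": [f.phase for f in fits],
            "slope": [f.slope for f in fits],
            "slope_se": [f.slope_se for f in fits],
            "ci_low": [f.ci95[0] for f in fits],
            "ci_high": [f.ci95[1] for f in fits],
            "n": [f.n for f in fits],
        }
    )
    diffs = []
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            a, b = fits[i], fits[j]
            diffs.append(
                {
                    "pair": f"{a.phase} - {b.phase}",
                    "difference": a.slope - b.slope,
                    "se": float(np.sqrt(a.slope_se**2 + b.slope_se**2)),
                }
            )
    ordered = sorted(fits, key=lambda f: f.slope)
    ordering = " < ".join(f.phase for f in ordered)
    shallowest = max(fits, key=lambda f: f.slope).phase
    return {
        "table": table,
        "differences": pd.DataFrame(diffs),
        "ordering": ordering,
        "shallowest": shallowest,
    }
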
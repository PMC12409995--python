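"""Differential-expression tables, signature selection, and DE plumbing.

Consumes the standard DESeq2 results layout (baseMean, log2FoldChange, lfcSE,
stat, pvalue, padj) without reimplementing the NB GLM: classification applies
the padj < 0.05 and |log2FC| > 1 thresholds, signature selection keeps the
low-uncertainty genes (lfcSE < 0.5), and ranking by `stat` feeds pre-ranked
enrichment tools. A Welch-t DE stage on log2(CPM+1) is provided purely so
synthetic end-to-end runs need no external DE tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


@dataclass
class SignatureSet:
    """An ordered disease-signature gene set plus the thresholds that made it."""

    gene_ids: list[str]
    selection_rule: dict

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def read_de_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a DESeq2-results-dialect TSV into a validated DataFrame.

    The index is gene_id. ``column_map`` renames non-standard headers onto the
    canonical names. Missing padj entries are tolerated (DESeq2 independent
    filtering leaves NAs) and counted; rows violating padj >= pvalue are
    flagged with a warning naming the genes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in DE_COLUMNS if c not in df.columns and c != "padj"]
    if missing:
        raise ValueError(f"DE table missing mandatory column(s): {missing}")
    for col in [c for c in DE_COLUMNS if c in df.columns]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric entries in column {col!r}")
    if "padj" not in df.columns:
        df["padj"] = np.nan
    n_na = int(df["padj"].isna().sum())
    if n_na:
        logger.info("%d genes have missing padj (treated as not significant)", n_na)
    both = df["padj"].notna() & df["pvalue"].notna()
    bad = df.index[both & (df["padj"] < df["pvalue"])]
    if len(bad):
        logger.warning("padj < pvalue for gene(s): %s", list(bad))
    return df


def write_de_table(df: pd.DataFrame, path) -> None:
    df.rename_axis("gene_id").to_csv(path, sep="\t")


def classify_genes(table: pd.DataFrame, lfc_thresh: float = 1.0,
                   padj_thresh: float = 0.05) -> pd.DataFrame:
    """Label genes up / down / ns by the strict significance thresholds.

    up: log2FC > lfc_thresh and padj < padj_thresh; down: log2FC < -lfc_thresh
    and padj < padj_thresh; everything else (including missing padj) is ns.
    """
    if lfc_thresh <= 0 or padj_thresh <= 0:
        raise ValueError("thresholds must be > 0")
    out = table.copy()
    sig = out["padj"].notna() & (out["padj"] < padj_thresh)
    out["label"] = np.where(
        sig & (out["log2FoldChange"] > lfc_thresh), "up",
        np.where(sig & (out["log2FoldChange"] < -lfc_thresh), "down", "ns"),
    )
    counts = out["label"].value_counts()
    logger.info("classification: %d up, %d down, %d ns",
                counts.get("up", 0), counts.get("down", 0), counts.get("ns", 0))
    return out


def select_signature(table: pd.DataFrame, lfcse_thresh: float = 0.5,
                     restrict_to: list[str] | None = None) -> SignatureSet:
    """Select the low-uncertainty signature: DE genes with lfcSE below threshold.

    ``restrict_to`` optionally intersects with an external gene list (e.g.
    pathway-cluster membership). Ordered by |log2FC| descending, ties broken
    by gene_id.
    """
    if "label" not in table.columns:
        raise ValueError("table must be classified first (no 'label' column)")
    sel = table[(table["label"] != "ns") & (table["lfcSE"] < lfcse_thresh)]
    if restrict_to is not None:
        sel = sel.loc[sel.index.intersection(restrict_to)]
    if sel.empty:
        raise ValueError(
            "empty signature: no DE gene passes lfcSE < "
            f"{lfcse_thresh}; consider relaxing the thresholds"
        )
    # |log2FC| descending, gene_id ascending on ties
    order = sel.iloc[
        np.lexsort((sel.index.to_numpy(), -sel["log2FoldChange"].abs().to_numpy()))
    ]
    return SignatureSet(
        gene_ids=list(order.index),
        selection_rule={
            "lfcse_thresh": lfcse_thresh,
            "restricted": restrict_to is not None,
        },
    )


def rank_for_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by the DE test statistic, descending, for pre-ranked GSEA.

    Ties preserve gene order. Returns a two-column (gene_id, stat) frame
    suitable for .rnk export.
    """
    if table["stat"].isna().any():
        missing = list(table.index[table["stat"].isna()])
        raise ValueError(f"missing stat for gene(s): {missing}")
    ranked = table.sort_values("stat", ascending=False, kind="mergesort")
    return ranked.reset_index()[[ranked.index.name or "index", "stat"]].rename(
        columns={ranked.index.name or "index": "gene_id"}
    )


class WelchDE(BaseEstimator):
    """Two-group Welch-t differential expression on log2(CPM+1) values.

    A lightweight internal DE stage (not an NB GLM): per gene, log2FC is the
    difference of group means on the log2(CPM+1) scale, lfcSE the Welch
    standard error, stat the Welch t, p-values from the t distribution with
    Satterthwaite df, and padj by Benjamini-Hochberg.

    fit(X, y) takes a samples x genes DataFrame and group labels; ``group``
    and ``reference`` name the two levels (log2FC is group minus reference).
    """

    def __init__(self, group: str = "baseline", reference: str = "control"):
        self.group = group
        self.reference = reference

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        X1 = X.loc[y == self.group]
        X2 = X.loc[y == self.reference]
        if len(X1) < 2 or len(X2) < 2:
            raise ValueError(
                f"each group needs >=2 samples (got {len(X1)} {self.group!r}, "
                f"{len(X2)} {self.reference!r})"
            )
        n1, n2 = len(X1), len(X2)
        m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
        v1, v2 = X1.var(axis=0, ddof=1), X2.var(axis=0, ddof=1)
        lfc = m1 - m2
        se = np.sqrt(v1 / n1 + v2 / n2)

        with np.errstate(divide="ignore", invalid="ignore"):
            stat = lfc / se
            df_num = (v1 / n1 + v2 / n2) ** 2
            df_den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            df = df_num / df_den
        # zero-variance genes: identical groups are null (t=0, p=1); a
        # nonzero difference with zero variance is maximally significant
        zero_se = se.to_numpy() == 0
        stat = stat.to_numpy()
        stat[zero_se & (lfc.to_numpy() == 0)] = 0.0
        stat[zero_se & (lfc.to_numpy() != 0)] = np.sign(lfc.to_numpy()[zero_se & (lfc.to_numpy() != 0)]) * np.inf
        df = df.to_numpy()
        df[~np.isfinite(df)] = n1 + n2 - 2
        pvalue = 2.0 * scipy.stats.t.sf(np.abs(stat), df)
        pvalue = np.clip(pvalue, 0.0, 1.0)
        padj = multipletests(pvalue, method="fdr_bh")[1]

        base_mean = (2.0 ** pd.concat([X1, X2]).mean(axis=0)) - 1.0
        self.results_ = pd.DataFrame(
            {
                "baseMean": base_mean.clip(lower=0.0),
                "log2FoldChange": lfc,
                "lfcSE": se,
                "stat": stat,
                "pvalue": pvalue,
                "padj": padj,
            },
            index=X.columns.rename("gene_id"),
        )
        return self


def simple_de(em: ExpressionMatrix, group: str = "baseline",
              reference: str = "control") -> pd.DataFrame:
    """Welch-t DE between two sample groups of a log2(CPM+1) matrix."""
    em.require_transform("log2cpm1")
    if em.sample_meta is None:
        raise ValueError("expression matrix carries no sample metadata")
    y = em.sample_meta.loc[list(em.values.columns), "group"].to_numpy()
    est = WelchDE(group=group, reference=reference).fit(em.values.T, y)
    return est.results_


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def volcano_transform(y):
    """Compress the upper tail of a volcano plot's -log10(padj) axis.

    Identity below 15; above, y maps to 15 + log2(y - 14), which is continuous
    at 15 (log2(1) = 0) and strictly increasing.
    """
    arr = np.asarray(y, dtype=float)
    if (arr < 0).any():
        raise ValueError("y must be >= 0 (it is a -log10 padj)")
    out = np.where(arr > 15, 15 + np.log2(np.maximum(arr - 14, 1e-300)), arr)
    return out if arr.ndim else float(out)
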
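"""Core in-memory containers for count and expression matrices.

Matrices are stored genes x samples (the orientation the on-disk TSV/MTX
formats use); the estimator classes transpose to the samples x features
orientation scikit-learn expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("control", "baseline", "treated")
VALID_TRANSFORMS = ("cpm", "log2cpm1", "zscore")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one column per sample_id; entries
        must be non-negative integers (read counts per gene).
    sample_meta
        DataFrame indexed by sample_id with columns ``group`` (one of
        control/baseline/treated), ``time_months`` and ``phase``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id(s): {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.isfinite(values).all():
                raise ValueError("counts contain non-finite entries")
            if (values < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        bad = set(self.sample_meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}; expected {VALID_GROUPS}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["group"] == group])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.sample_meta)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix tagged with the transform that made it.

    ``norm_stats`` carries the per-gene (mu, sigma) used for z-scoring and is
    only populated when ``transform == "zscore"``.
    """

    values: pd.DataFrame
    transform: str
    sample_meta: pd.DataFrame | None = None
    norm_stats: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.transform not in VALID_TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; expected one of {VALID_TRANSFORMS}"
            )
        if self.transform == "zscore":
            if self.norm_stats is None:
                raise ValueError("zscore matrices must carry norm_stats (mu, sigma)")
            if (self.norm_stats["sigma"] <= 0).any():
                raise ValueError("sigma must be > 0 for every retained gene")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def require_transform(self, expected: str) -> None:
        if self.transform != expected:
            raise ValueError(
                f"expected a {expected!r} matrix, got {self.transform!r}"
            )
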
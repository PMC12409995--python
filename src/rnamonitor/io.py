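"""Reading and writing the on-disk formats.

Counts travel either as a dense TSV (gene rows, header = sample ids) or as a
MatrixMarket coordinate triplet with ``genes.tsv`` / ``samples.tsv`` sidecars.
Sample metadata is a TSV with columns sample_id, group, time_months, phase.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix

MTX_MATRIX = "matrix.mtx"
MTX_GENES = "genes.tsv"
MTX_SAMPLES = "samples.tsv"


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return meta.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_counts(path, format: str = "tsv", meta_path=None) -> CountMatrix:
    """Load a validated :class:`CountMatrix` from ``tsv`` or ``mtx`` format.

    For ``mtx``, ``path`` is the directory holding matrix.mtx, genes.tsv and
    samples.tsv. ``meta_path`` points to the sample-metadata TSV; if omitted,
    a minimal all-``treated`` metadata table is synthesised.
    """
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        d = Path(path)
        mat = scipy.io.mmread(d / MTX_MATRIX)
        genes = pd.read_csv(d / MTX_GENES, sep="\t", header=None)[0].astype(str)
        samples = pd.read_csv(d / MTX_SAMPLES, sep="\t", header=None)[0].astype(str)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match registries "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        counts = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")

    vals = counts.to_numpy()
    if vals.size and not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integral")
    counts = counts.astype(np.int64)

    if meta_path is not None:
        meta = read_metadata(meta_path)
    else:
        meta = pd.DataFrame(
            {"group": "treated", "time_months": np.nan, "phase": ""},
            index=counts.columns.rename("sample_id"),
        )
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path, format: str = "tsv") -> None:
    """Write counts as TSV or as an MTX triplet directory."""
    if format == "tsv":
        cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif format == "mtx":
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(d / MTX_MATRIX), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        pd.Series(cm.counts.index).to_csv(d / MTX_GENES, sep="\t", index=False, header=False)
        pd.Series(cm.counts.columns).to_csv(d / MTX_SAMPLES, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"time_months", "phase"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical series missing column(s): {sorted(missing)}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json_summary(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
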
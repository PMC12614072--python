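"""Readers and writers for delimited expression, label and length tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import ExpressionMatrix, Unit

__all__ = [
    "read_expression",
    "read_expression_mtx",
    "write_expression",
    "read_labels",
    "read_gene_lengths",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, unit: Unit | str) -> ExpressionMatrix:
    """Read a delimited genes x samples table.

    Expects a header row of sample ids and a first column of gene ids;
    tab-separated unless the file ends in ``.csv``. Duplicate gene ids,
    negative values and non-numeric cells are errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file has no data: {path}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:3]
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric values in expression file {path}") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"missing or non-finite values in {path}")
    return ExpressionMatrix.from_frame(df, unit)


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    unit: Unit | str,
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix plus row/column id files.

    The id files are one identifier per line; rows are genes, columns
    samples (the matrix is densified — bulk cohorts are small enough).
    """
    m = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(m):
        m = m.toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    return ExpressionMatrix(np.asarray(m, dtype=float), genes, samples, unit)


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    X.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, subtype) table into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file needs two columns (sample_id, subtype): {path}")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="subtype")
    if s.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in label file {path}")
    return s


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column (gene_id, length_bp) table into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"length file needs two columns (gene_id, length_bp): {path}")
    s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0].astype(str).to_numpy())
    if (s <= 0).any() or not np.all(np.isfinite(s.to_numpy())):
        raise ValueError(f"gene lengths must be positive and finite: {path}")
    if s.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in length file {path}")
    return s
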
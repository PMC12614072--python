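"""Expression-matrix container with unit tracking.

The container is deliberately thin: a dense genes x samples array plus
identifiers and a unit tag (``counts``, ``fpkm``, ``tpm`` or ``log2tpm``).
Every preprocessing step returns a new instance with an updated tag, so the
pipeline state is always explicit and a model can refuse input in the wrong
unit instead of silently mis-normalizing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Unit", "ExpressionMatrix"]


class Unit(str, enum.Enum):
    """Unit tag for an expression matrix."""

    COUNTS = "counts"
    FPKM = "fpkm"
    TPM = "tpm"
    LOG2TPM = "log2tpm"


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix.

    Parameters
    ----------
    values
        Non-negative array of shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    unit
        One of :class:`Unit` (or its string value).
    """

    values: np.ndarray
    gene_ids: list[str] = field(repr=False)
    sample_ids: list[str] = field(repr=False)
    unit: Unit

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.unit = Unit(self.unit)
        d, n = self.values.shape
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {d} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if d == 0 or n == 0:
            raise ValueError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if (self.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return a genes x samples DataFrame (index = gene ids)."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: Unit | str) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            unit=Unit(unit),
        )

    def with_values(self, values: np.ndarray, unit: Unit | str) -> "ExpressionMatrix":
        """New matrix with the same identifiers but different values/unit."""
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids), Unit(unit))

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.unit,
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Column-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.unit,
        )
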
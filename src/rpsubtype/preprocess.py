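"""Normalization pipeline: prevalence filter, TPM conversion, log transform.

All public functions take and return :class:`~rpsubtype.matrix.ExpressionMatrix`
instances; the unit tag enforces that each step sees the unit it expects.
The canonical training representation is ``log2(TPM + 1)``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, Unit

__all__ = [
    "filter_genes",
    "counts_to_tpm",
    "fpkm_to_tpm",
    "log_transform",
    "to_log2tpm",
    "align_to_genes",
]


def filter_genes(
    X: ExpressionMatrix,
    min_fraction: float = 0.75,
    expression_cutoff: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes expressed in at least ``min_fraction`` of samples.

    A gene counts as expressed in a sample when its value exceeds
    ``expression_cutoff`` (default 0, i.e. any nonzero signal). The
    prevalence threshold is ``ceil(min_fraction * n_samples)`` so that
    "at least 75%" is literal at every sample count. Gene order is
    preserved; the sample set is unchanged.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = X.n_samples
    needed = math.ceil(min_fraction * n)
    expressed = (X.values > expression_cutoff).sum(axis=1)
    keep = expressed >= needed
    if not keep.any():
        raise ValueError("prevalence filter removed every gene")
    return X.subset_genes(keep)


def counts_to_tpm(X: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    Per sample: ``rate_g = count_g / length_kb_g`` then
    ``TPM_g = rate_g / sum_g rate_g * 1e6``. Columns with zero total
    counts stay all-zero. ``lengths`` maps gene id -> effective length
    in base pairs; every gene in ``X`` must be present.
    """
    if X.unit is not Unit.COUNTS:
        raise ValueError(f"counts_to_tpm requires counts, got {X.unit.value}")
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in X.gene_ids if g not in lengths.index]
    if missing:
        raise KeyError(f"missing gene lengths for {len(missing)} genes, e.g. {missing[:3]}")
    len_bp = lengths.loc[X.gene_ids].to_numpy()
    if (len_bp <= 0).any() or not np.all(np.isfinite(len_bp)):
        raise ValueError("gene lengths must be positive and finite")
    rate = X.values / (len_bp[:, None] / 1000.0)
    colsum = rate.sum(axis=0)
    scale = np.divide(1e6, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    return X.with_values(rate * scale[None, :], Unit.TPM)


def fpkm_to_tpm(X: ExpressionMatrix) -> ExpressionMatrix:
    """Renormalize FPKM so each sample column sums to one million.

    FPKM already divides by gene length, so TPM is a within-sample
    rescaling: ``TPM_g = FPKM_g / sum_g FPKM_g * 1e6``.
    """
    if X.unit is not Unit.FPKM:
        raise ValueError(f"fpkm_to_tpm requires fpkm, got {X.unit.value}")
    colsum = X.values.sum(axis=0)
    scale = np.divide(1e6, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    return X.with_values(X.values * scale[None, :], Unit.TPM)


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(TPM + 1)``; zero maps to zero."""
    if X.unit is not Unit.TPM:
        raise ValueError(f"log_transform requires tpm, got {X.unit.value}")
    return X.with_values(np.log2(X.values + 1.0), Unit.LOG2TPM)


def to_log2tpm(X: ExpressionMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Convert a matrix in any supported unit to log2(TPM+1).

    Counts require a gene-length table; FPKM and TPM do not. A matrix
    already in log2tpm passes through unchanged.
    """
    if X.unit is Unit.LOG2TPM:
        return X
    if X.unit is Unit.TPM:
        return log_transform(X)
    if X.unit is Unit.FPKM:
        return log_transform(fpkm_to_tpm(X))
    if lengths is None:
        raise ValueError("converting counts to TPM requires a gene-length table")
    return log_transform(counts_to_tpm(X, lengths))


def align_to_genes(
    X: ExpressionMatrix,
    gene_ids: list[str],
    min_coverage: float = 0.9,
    fill_missing: bool = False,
) -> ExpressionMatrix:
    """Reorder ``X`` onto a reference gene list (e.g. a model's training genes).

    Genes are matched by id. If fewer than ``min_coverage`` of the
    reference genes are present the call errors — a projection applied to
    a badly covered matrix is meaningless. With ``fill_missing=True``,
    absent reference genes are zero-filled instead (coverage is still
    enforced); this is opt-in because silent zero-fill perturbs
    projections unpredictably.
    """
    pos = {g: i for i, g in enumerate(X.gene_ids)}
    present = [g for g in gene_ids if g in pos]
    coverage = len(present) / len(gene_ids)
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.1%} of {len(gene_ids)} reference genes present "
            f"(minimum {min_coverage:.0%})"
        )
    if len(present) == len(gene_ids):
        idx = np.array([pos[g] for g in gene_ids])
        return ExpressionMatrix(X.values[idx], list(gene_ids), list(X.sample_ids), X.unit)
    if not fill_missing:
        missing = [g for g in gene_ids if g not in pos][:3]
        raise ValueError(
            f"{len(gene_ids) - len(present)} reference genes absent (e.g. {missing}); "
            "pass fill_missing=True to zero-fill"
        )
    out = np.zeros((len(gene_ids), X.n_samples))
    for i, g in enumerate(gene_ids):
        j = pos.get(g)
        if j is not None:
            out[i] = X.values[j]
    return ExpressionMatrix(out, list(gene_ids), list(X.sample_ids), X.unit)
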
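"""Very sparse random projection and distance-preservation diagnostics.

The projection matrix R (d x D) has i.i.d. entries

    +sqrt(p)  with probability 1/(2p)
     0        with probability 1 - 1/p
    -sqrt(p)  with probability 1/(2p)

which has zero mean and unit variance for any sparsity parameter p >= 1,
so by the Johnson-Lindenstrauss argument the scaled map A = R T / sqrt(d)
approximately preserves pairwise Euclidean distances between the N sample
columns of T. The default p = sqrt(D) gives a nonzero fraction of
1/sqrt(D) — a few permille for transcriptome-sized D — making the
projection cheap to store and apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .matrix import ExpressionMatrix

__all__ = [
    "ProjectionMatrix",
    "ProjectedData",
    "make_rp_matrix",
    "project",
    "distance_preservation_pcc",
    "dimension_sweep_report",
    "reduce_dimension",
]


@dataclass
class ProjectionMatrix:
    """A d x D sparse random matrix with entries in {-sqrt(p), 0, +sqrt(p)}."""

    matrix: sp.csr_matrix = field(repr=False)
    d: int
    D: int
    p: float
    seed: int

    @property
    def nonzero_fraction(self) -> float:
        return self.matrix.nnz / (self.d * self.D)


@dataclass
class ProjectedData:
    """d x N projected data with the provenance needed to regenerate it."""

    values: np.ndarray
    d: int
    D: int
    p: float
    seed: int
    sample_ids: list[str] = field(default_factory=list, repr=False)


def make_rp_matrix(D: int, d: int, p: float | None = None, seed: int = 0) -> ProjectionMatrix:
    """Draw a very sparse random projection matrix.

    Parameters
    ----------
    D, d
        Source and target dimension, ``1 <= d < D``.
    p
        Sparsity parameter (>= 1); entries are nonzero with probability
        1/p. Default ``sqrt(D)``.
    seed
        Seed for an independent ``numpy`` Generator; identical arguments
        reproduce the matrix bit-for-bit.
    """
    if p is None:
        p = math.sqrt(D)
    if not (1 <= d < D):
        raise ValueError(f"need 1 <= d < D, got d={d}, D={D}")
    if p < 1:
        raise ValueError(f"sparsity parameter p must be >= 1, got {p}")
    rng = np.random.default_rng(seed)
    total = d * D
    # Exact i.i.d. Bernoulli construction: draw the nonzero count, then
    # nonzero positions uniformly without replacement, then fair signs.
    nnz = int(rng.binomial(total, 1.0 / p))
    flat = rng.choice(total, size=nnz, replace=False)
    signs = rng.integers(0, 2, size=nnz) * 2 - 1
    rows, cols = np.divmod(flat, D)
    m = sp.coo_matrix(
        (signs * math.sqrt(p), (rows, cols)), shape=(d, D), dtype=float
    ).tocsr()
    return ProjectionMatrix(matrix=m, d=d, D=D, p=float(p), seed=int(seed))


def _as_array(T: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(T, ExpressionMatrix):
        return T.values
    return np.asarray(T, dtype=float)


def project(R: ProjectionMatrix, T: ExpressionMatrix | np.ndarray) -> ProjectedData:
    """Project a D x N data matrix: ``A = R T / sqrt(d)`` (d x N).

    The 1/sqrt(d) factor makes the squared distance between projected
    columns an unbiased estimate of the original squared distance.
    """
    values = _as_array(T)
    if values.shape[0] != R.D:
        raise ValueError(f"projection expects {R.D} genes, data has {values.shape[0]}")
    A = (R.matrix @ values) / math.sqrt(R.d)
    sample_ids = list(T.sample_ids) if isinstance(T, ExpressionMatrix) else []
    return ProjectedData(values=A, d=R.d, D=R.D, p=R.p, seed=R.seed, sample_ids=sample_ids)


def distance_preservation_pcc(
    T: ExpressionMatrix | np.ndarray,
    A: ProjectedData | np.ndarray,
) -> float:
    """Pearson correlation of pairwise sample distances before/after projection.

    Both inputs are features x samples; the N(N-1)/2 Euclidean distances
    between sample columns are compared.
    """
    orig = _as_array(T)
    proj = A.values if isinstance(A, ProjectedData) else np.asarray(A, dtype=float)
    if orig.shape[1] != proj.shape[1]:
        raise ValueError("original and projected data have different sample counts")
    n = orig.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a distance correlation")
    d_orig = pdist(orig.T)
    d_proj = pdist(proj.T)
    if np.std(d_orig) == 0 or np.std(d_proj) == 0:
        raise ValueError("zero-variance distance vector")
    return float(pearsonr(d_orig, d_proj)[0])


def reduce_dimension(
    T: ExpressionMatrix | np.ndarray,
    d: int,
    method: str = "rp",
    seed: int = 0,
    p: float | None = None,
) -> np.ndarray:
    """Reduce features x samples data to d x samples with a named backend.

    ``rp`` is the native sparse random projection; ``pca`` and ``umap``
    are thin adapters over scikit-learn / umap-learn for comparison runs
    (``tsne`` is supported only for d <= 3, its usual regime).
    """
    X = _as_array(T)
    if method == "rp":
        R = make_rp_matrix(X.shape[0], d, p=p, seed=seed)
        return project(R, X).values
    if method == "pca":
        from sklearn.decomposition import PCA

        k = min(d, X.shape[1] - 1, X.shape[0])
        return PCA(n_components=k, random_state=seed).fit_transform(X.T).T
    if method == "tsne":
        if d > 3:
            raise ValueError("tsne adapter supports d <= 3 only")
        from sklearn.manifold import TSNE

        n = X.shape[1]
        perp = min(30.0, max(2.0, (n - 1) / 3))
        return TSNE(n_components=d, random_state=seed, perplexity=perp, init="pca").fit_transform(X.T).T
    if method == "umap":
        import umap

        return umap.UMAP(n_components=d, random_state=seed).fit_transform(X.T).T
    raise ValueError(f"unknown reduction method {method!r}")


def dimension_sweep_report(
    T: ExpressionMatrix | np.ndarray,
    dims: list[int],
    p: float | None = None,
    seeds: list[int] | tuple[int, ...] = (0,),
    method: str = "rp",
) -> pd.DataFrame:
    """Distance-preservation PCC per target dimension, averaged over seeds.

    Duplicate dimensions collapse to unique sorted values. Returns a
    DataFrame with columns ``dim``, ``mean_pcc``, ``sd_pcc``, ``n_seeds``.
    """
    if not dims:
        raise ValueError("dims must be nonempty")
    X = _as_array(T)
    dims = sorted(set(int(v) for v in dims))
    rows = []
    for d in dims:
        pccs = []
        for s in seeds:
            reduced = reduce_dimension(X, d, method=method, seed=int(s), p=p)
            pccs.append(distance_preservation_pcc(X, reduced))
        rows.append(
            {
                "dim": d,
                "mean_pcc": float(np.mean(pccs)),
                "sd_pcc": float(np.std(pccs, ddof=1)) if len(pccs) > 1 else 0.0,
                "n_seeds": len(pccs),
            }
        )
    return pd.DataFrame(rows)
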
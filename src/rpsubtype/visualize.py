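"""Prediction-informed 2-D visualization.

The visualization matrix concatenates two Z-scored blocks per sample: the
d projected expression features, weighted by w, and the C one-hot encoded
predicted subtypes. With w > 1 the embedding emphasizes the reduced
feature space (global expression structure); with 0 < w < 1 it
emphasizes the predicted subtype assignments, pulling samples of one
predicted class together. The combined matrix feeds a stochastic
neighbor embedding (t-SNE) to produce 2-D coordinates.

Z-scoring uses the population (divide-by-N) standard deviation;
zero-variance columns map to all-zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .projection import ProjectedData

__all__ = [
    "one_hot",
    "zscore_columns",
    "VisualizationMatrix",
    "build_vis_matrix",
    "embed_2d",
    "plot_embedding",
]


def one_hot(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """N x C 0/1 indicator matrix of labels against class_order."""
    index = {str(c): i for i, c in enumerate(class_order)}
    out = np.zeros((len(labels), len(class_order)))
    for r, lab in enumerate(labels):
        try:
            out[r, index[str(lab)]] = 1.0
        except KeyError:
            raise ValueError(f"label {lab!r} not in class_order") from None
    return out


def zscore_columns(M: np.ndarray) -> np.ndarray:
    """Column-wise Z-score with population sd; constant columns become zeros."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to Z-score")
    mean = M.mean(axis=0)
    sd = M.std(axis=0)  # ddof=0
    out = np.zeros_like(M)
    ok = sd > 0
    out[:, ok] = (M[:, ok] - mean[ok]) / sd[ok]
    return out


@dataclass
class VisualizationMatrix:
    """N x (d + C): [ w * zscore(features) | zscore(one-hot predictions) ]."""

    values: np.ndarray = field(repr=False)
    n_features: int
    n_classes: int
    weight_ratio: float
    metadata: dict = field(default_factory=dict)


def build_vis_matrix(
    F: ProjectedData | np.ndarray,
    Y_onehot: np.ndarray,
    w: float = 1.0,
) -> VisualizationMatrix:
    """Combine projected features and one-hot predictions into one matrix.

    ``F`` is d x N projected data (or any features x samples array);
    ``Y_onehot`` is N x C. Both blocks are Z-scored per column over the
    N samples, the feature block is scaled by the weight ratio w, and
    the blocks are concatenated with samples in rows.
    """
    feats = F.values if isinstance(F, ProjectedData) else np.asarray(F, dtype=float)
    feats = feats.T  # samples in rows
    Y_onehot = np.asarray(Y_onehot, dtype=float)
    if feats.shape[0] != Y_onehot.shape[0]:
        raise ValueError(
            f"feature block has {feats.shape[0]} samples, prediction block {Y_onehot.shape[0]}"
        )
    if w <= 0:
        raise ValueError("weight ratio w must be > 0")
    V = np.hstack([w * zscore_columns(feats), zscore_columns(Y_onehot)])
    return VisualizationMatrix(
        values=V,
        n_features=feats.shape[1],
        n_classes=Y_onehot.shape[1],
        weight_ratio=float(w),
        metadata={"zscore": "population (ddof=0)"},
    )


def embed_2d(
    V: VisualizationMatrix | np.ndarray,
    seed: int = 0,
    perplexity: float | None = None,
) -> tuple[np.ndarray, dict]:
    """t-SNE embedding of the visualization matrix rows to 2-D.

    The neighborhood size defaults to ``min(30, (N - 1) / 3)`` (t-SNE
    requires perplexity < N). Deterministic given the seed. Returns
    ``(coords, params)`` where coords is N x 2.
    """
    from sklearn.manifold import TSNE

    X = V.values if isinstance(V, VisualizationMatrix) else np.asarray(V, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to embed")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed),
        init="pca",
        learning_rate="auto",
    )
    coords = tsne.fit_transform(X)
    params = {"method": "tsne", "perplexity": float(perplexity), "seed": int(seed)}
    return np.asarray(coords, dtype=float), params


def plot_embedding(
    coords: np.ndarray,
    labels: Sequence[str],
    out_path: str | Path,
    title: str | None = None,
) -> Path:
    """Scatter plot of the embedding colored by subtype, with a legend.

    Colors are assigned by sorted label name, so the same subtypes get
    the same colors across plots. SVG output is byte-stable for fixed
    input (fixed hash salt, no timestamp metadata).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=float)
    labels = [str(l) for l in labels]
    if len(labels) == 0:
        raise ValueError("empty label set")
    if coords.shape[0] != len(labels):
        raise ValueError("coords and labels differ in length")
    classes = sorted(set(labels))
    cmap = plt.get_cmap("tab20")
    colors = {c: cmap(i % 20) for i, c in enumerate(classes)}

    with plt.rc_context({"svg.hashsalt": "rpsubtype"}):
        fig, ax = plt.subplots(figsize=(8, 6))
        arr = np.asarray(labels)
        for c in classes:
            mask = arr == c
            ax.scatter(coords[mask, 0], coords[mask, 1], s=14, color=colors[c], label=c)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        if title:
            ax.set_title(title)
        ax.legend(fontsize=7, markerscale=1.2, loc="center left", bbox_to_anchor=(1.0, 0.5))
        fig.tight_layout()
        out_path = Path(out_path)
        kwargs = {"metadata": {"Date": None}} if out_path.suffix.lower() == ".svg" else {}
        fig.savefig(out_path, **kwargs)
        plt.close(fig)
    return out_path
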
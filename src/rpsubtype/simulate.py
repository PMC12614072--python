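"""Synthetic bulk-expression cohorts with planted subtype structure.

The generator emulates the features of a molecular-subtyping cohort that
the pipeline actually exercises: imbalanced class sizes, disjoint blocks
of marker genes shifted upward on the log2 scale in their class, a
shared log-normal baseline, per-sample library-size variation, Poisson
count noise, and a zero-inflated gene fraction that the 75% prevalence
filter is expected to remove. Counts (not TPM) are produced so the full
preprocessing path (filter -> TPM -> log2) is testable; gene lengths are
emitted alongside. It makes no attempt to mimic real co-expression
covariance or fusion-transcript signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, Unit
from .subtypes import default_scheme

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_expression",
    "make_cohort_like",
    "gaussian_clusters",
    "write_fixture_dir",
]

# Class sizes for the cohort-like preset: 20 classes, 500 samples, the three
# largest at 18.6% / 15.4% / 10.8% and a long tail floored at >= 5 samples.
_COHORT_SIZES = (93, 77, 54, 40, 35, 30, 25, 22, 20, 18, 15, 12, 11, 9, 8, 7, 6, 6, 6, 6)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    effect_size is the additive log2-scale mean shift of a class's
    marker genes; noise_sd the per-entry log2 biological noise;
    library_size_variation the sd of the log-normal per-sample depth
    factor; zero_inflated_fraction of genes get entries dropped to zero
    with probability dropout_rate (putting them below a 75% prevalence
    filter in expectation).
    """

    n_genes: int = 2000
    class_sizes: tuple[int, ...] = (60, 40, 25, 15, 10)
    markers_per_class: int = 20
    effect_size: float = 2.0
    baseline_mean: float = 5.0
    noise_sd: float = 1.0
    library_size_variation: float = 0.2
    zero_inflated_fraction: float = 0.1
    dropout_rate: float = 0.5
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.class_sizes):
            raise ValueError("every class needs at least 2 samples")
        if self.markers_per_class * len(self.class_sizes) > self.n_genes:
            raise ValueError("more marker genes than genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.zero_inflated_fraction < 1:
            raise ValueError("zero_inflated_fraction must be in [0, 1)")
        if self.class_names is not None and len(self.class_names) != len(self.class_sizes):
            raise ValueError("class_names length must match class_sizes")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    labels: pd.Series = field(repr=False)
    gene_lengths: pd.Series = field(repr=False)
    marker_map: dict[str, list[str]] = field(repr=False)


def generate_expression(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one synthetic counts cohort from a spec; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.class_sizes)
    n = int(sum(spec.class_sizes))
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    names = (
        list(spec.class_names)
        if spec.class_names is not None
        else [f"class_{c:02d}" for c in range(n_classes)]
    )
    labels = np.repeat(names, spec.class_sizes)

    # disjoint marker blocks at the head of the gene list
    marker_map = {
        names[c]: gene_ids[c * spec.markers_per_class : (c + 1) * spec.markers_per_class]
        for c in range(n_classes)
    }
    n_marker = spec.markers_per_class * n_classes

    baseline = np.clip(rng.normal(spec.baseline_mean, 1.5, size=spec.n_genes), 0.5, None)
    log2_mu = np.tile(baseline[:, None], (1, n))
    for c, name in enumerate(names):
        cols = np.flatnonzero(labels == name)
        rows = np.arange(c * spec.markers_per_class, (c + 1) * spec.markers_per_class)
        log2_mu[np.ix_(rows, cols)] += spec.effect_size
    log2_expr = log2_mu + rng.normal(0.0, spec.noise_sd, size=log2_mu.shape)

    lengths = pd.Series(
        rng.integers(500, 5001, size=spec.n_genes).astype(float), index=gene_ids
    )
    depth = np.exp(rng.normal(0.0, spec.library_size_variation, size=n))
    # expected counts scale with expression level, gene length and depth
    lam = (2.0**log2_expr) * (lengths.to_numpy()[:, None] / 1000.0) * depth[None, :] * 0.5
    counts = rng.poisson(lam).astype(float)

    n_zi = int(round(spec.zero_inflated_fraction * spec.n_genes))
    if n_zi > 0:
        zi_pool = np.arange(n_marker, spec.n_genes)
        zi_genes = rng.choice(zi_pool, size=min(n_zi, len(zi_pool)), replace=False)
        drop = rng.random((len(zi_genes), n)) < spec.dropout_rate
        counts[zi_genes] = np.where(drop, 0.0, counts[zi_genes])

    X = ExpressionMatrix(counts, gene_ids, sample_ids, Unit.COUNTS)
    return SyntheticDataset(
        expression=X,
        labels=pd.Series(labels, index=sample_ids, name="subtype"),
        gene_lengths=lengths,
        marker_map=marker_map,
    )


def make_cohort_like(
    seed: int = 0,
    n_genes: int = 5000,
    effect_size: float = 4.0,
    noise_sd: float = 0.5,
) -> SyntheticDataset:
    """A 20-class, 500-sample cohort echoing the real subtype imbalance.

    Class sizes follow the shape of the pediatric B-ALL cohort
    distribution (largest classes at 18.6% / 15.4% / 10.8%, long tail
    floored at 5 samples) and carry the 20 harmonized subtype names in
    prevalence order. Desk-scale: ~5,000 genes.
    """
    scheme = default_scheme()
    names = (
        "Ph-like", "High hyperdiploid", "ETV6-RUNX1", "PAX5alt", "DUX4",
        "Ph", "TCF3-PBX1", "ZNF384 Group", "KMT2A Group", "ETV6-RUNX1-like",
        "Low hyperdiploid", "MEF2D", "Low hypodiploid", "iAMP21", "NUTM1",
        "BCL2/MYC", "PAX5 P80R", "IKZF1 N159Y", "Near haploid", "HLF",
    )
    assert set(names) == set(scheme.labels)
    spec = SyntheticSpec(
        n_genes=n_genes,
        class_sizes=_COHORT_SIZES,
        markers_per_class=20,
        effect_size=effect_size,
        baseline_mean=5.0,
        noise_sd=noise_sd,
        library_size_variation=0.2,
        zero_inflated_fraction=0.1,
        class_names=names,
        seed=seed,
    )
    return generate_expression(spec)


def gaussian_clusters(
    D: int = 2000,
    N: int = 100,
    n_clusters: int = 4,
    shift: float = 2.0,
    marker_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Clustered Gaussian data (features x samples) for distance diagnostics.

    Each cluster shifts a random ``marker_fraction`` of the D features by
    ``shift`` over unit-variance Gaussian noise — the structure that makes
    pairwise sample distances heterogeneous, as in a subtype cohort. (A
    fully isotropic Gaussian is a degenerate benchmark for distance
    preservation: its pairwise distances concentrate so tightly that the
    correlation is dominated by projection noise no matter how faithful
    the projection is.) Returns ``(data, cluster_assignments)``.
    """
    rng = np.random.default_rng(seed)
    means = np.zeros((n_clusters, D))
    n_mark = max(1, int(round(marker_fraction * D)))
    for c in range(n_clusters):
        means[c, rng.choice(D, n_mark, replace=False)] = shift
    z = np.arange(N) % n_clusters
    X = means[z] + rng.normal(size=(N, D))
    return X.T, z


def write_fixture_dir(data: SyntheticDataset, out_dir: str | Path) -> None:
    """Write expr.tsv, labels.tsv, lengths.tsv and truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.expression.to_frame().to_csv(out / "expr.tsv", sep="\t", index_label="gene_id")
    data.labels.rename_axis("sample_id").reset_index().to_csv(out / "labels.tsv", sep="\t", index=False)
    data.gene_lengths.rename("length_bp").rename_axis("gene_id").reset_index().to_csv(
        out / "lengths.tsv", sep="\t", index=False
    )
    (out / "truth.json").write_text(json.dumps({"marker_map": data.marker_map}, indent=1))
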
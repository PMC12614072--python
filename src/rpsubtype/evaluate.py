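"""Cross-validation and hold-out harnesses for the projection ensemble.

Within one CV run the M projection matrices are drawn once and shared
across folds (a data-independent random projection cannot leak label
information between folds); only the SVMs are refit per fold. This makes
repeated CV affordable: projecting the full matrix is done M times, not
M x k times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .ensemble import _fit_calibrated_svc
from .matrix import ExpressionMatrix, Unit
from .metrics import MetricsReport, compute_report
from .projection import make_rp_matrix, project
from .subtypes import SubtypeScheme

__all__ = [
    "stratified_fold_indices",
    "holdout_split",
    "cross_validate",
    "repeated_cv",
    "CVResult",
    "RepeatedCVResult",
    "ensemble_vs_individual",
]


def _as_label_array(y, sample_ids: list[str] | None = None) -> np.ndarray:
    if isinstance(y, pd.Series) and sample_ids is not None:
        y = y.reindex(sample_ids).to_numpy()
        if pd.isna(y).any():
            raise ValueError("labels missing for some samples")
    return np.asarray(y, dtype=object).astype(str)


def stratified_fold_indices(y, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Test-index arrays for k stratified folds.

    Samples of each class are shuffled and dealt round-robin across
    folds (starting at a rotating offset so fold sizes stay even), which
    keeps per-fold class proportions within one sample of the stratified
    target and handles classes smaller than k gracefully: such a class
    simply misses some test folds. A warning lists any class smaller
    than k, since its fold estimates rest on single samples.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = _as_label_array(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    small = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            small.append(str(cls))
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(offset + j) % k].append(int(i))
        offset = (offset + len(idx)) % k
    if small:
        warnings.warn(
            f"classes with fewer than {k} samples spread over a subset of folds: {small}",
            UserWarning,
            stacklevel=2,
        )
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def holdout_split(y, fraction: float = 0.30, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train_idx, test_idx).

    The test size is ``round(fraction * N)``, apportioned across classes
    by largest remainder of ``fraction * n_c``; every class keeps at
    least one training sample.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    y = _as_label_array(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = int(round(fraction * n))
    quota = fraction * counts
    take = np.floor(quota).astype(int)
    # never empty a class out of the training set
    take = np.minimum(take, counts - 1)
    remainder = quota - np.floor(quota)
    order = np.argsort(-remainder, kind="stable")
    for i in order:
        if take.sum() >= target:
            break
        if take[i] < counts[i] - 1:
            take[i] += 1
    test_parts = []
    for cls, t in zip(classes, take):
        idx = rng.permutation(np.flatnonzero(y == cls))
        test_parts.append(idx[:t])
    test_idx = np.sort(np.concatenate(test_parts))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


@dataclass
class CVResult:
    """Pooled out-of-fold predictions from one cross-validation run."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray = field(repr=False)
    class_order: list[str]
    member_preds: np.ndarray | None = field(default=None, repr=False)  # (M, N) labels

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def member_accuracies(self) -> np.ndarray:
        if self.member_preds is None:
            raise ValueError("run cross_validate with collect_members=True")
        return (self.member_preds == self.y_true[None, :]).mean(axis=1)

    def report(self, scheme: SubtypeScheme | None = None) -> MetricsReport:
        return compute_report(self.y_true, self.y_pred, self.class_order, scheme)


def cross_validate(
    X: ExpressionMatrix,
    y,
    k: int = 5,
    d: int = 1200,
    M: int = 30,
    seed: int = 0,
    regularization: float = 1.0,
    p: float | None = None,
    collect_members: bool = False,
) -> CVResult:
    """One stratified k-fold CV run of the projection ensemble.

    Returns the pooled out-of-fold ensemble predictions (and, with
    ``collect_members=True``, every member's own out-of-fold argmax
    labels, for ensemble-vs-individual comparisons at no extra fits).
    """
    if X.unit is not Unit.LOG2TPM:
        raise ValueError(f"cross_validate requires log2tpm input, got {X.unit.value}")
    y = _as_label_array(y, X.sample_ids)
    n = X.n_samples
    class_order = sorted(np.unique(y))
    projections = [make_rp_matrix(X.n_genes, d, p=p, seed=int(seed) + m) for m in range(1, M + 1)]
    A_all = [project(R, X).values.T for R in projections]  # each N x d
    folds = stratified_fold_indices(y, k=k, seed=int(seed))

    C = len(class_order)
    scores = np.zeros((n, C))
    member_scores = np.zeros((M, n, C)) if collect_members else None
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_tr = y[train_idx]
        for m in range(M):
            clf = _fit_calibrated_svc(
                A_all[m][train_idx], y_tr, regularization, int(seed) + m + 1
            )
            proba = clf.predict_proba(A_all[m][test_idx])
            # map the member's class columns onto the global class order
            col = {c: j for j, c in enumerate(clf.classes_)}
            full = np.zeros((len(test_idx), C))
            for j, c in enumerate(class_order):
                if c in col:
                    full[:, j] = proba[:, col[c]]
            scores[test_idx] += full / M
            if collect_members:
                member_scores[m, test_idx] = full
    y_pred = np.array([class_order[i] for i in scores.argmax(axis=1)], dtype=object).astype(str)
    member_preds = None
    if collect_members:
        member_preds = np.array(
            [[class_order[i] for i in ms.argmax(axis=1)] for ms in member_scores],
            dtype=object,
        ).astype(str)
    return CVResult(
        y_true=y, y_pred=y_pred, scores=scores, class_order=class_order, member_preds=member_preds
    )


@dataclass
class RepeatedCVResult:
    reports: list[MetricsReport]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "accuracy": r.aggregate.accuracy,
                "f1_weighted": r.aggregate.f1_weighted,
                "f1_macro": r.aggregate.f1_macro,
                "mcc": r.aggregate.mcc,
            }
            for r in self.reports
        ]
        df = pd.DataFrame(rows)
        return df.agg(["mean", "std"])


def repeated_cv(
    X: ExpressionMatrix,
    y,
    k: int = 5,
    repeats: int = 100,
    d: int = 1200,
    M: int = 30,
    seed: int = 0,
    regularization: float = 1.0,
    p: float | None = None,
    scheme: SubtypeScheme | None = None,
) -> RepeatedCVResult:
    """Repeated stratified k-fold CV, re-randomized each repeat."""
    reports = []
    for r in range(repeats):
        res = cross_validate(
            X, y, k=k, d=d, M=M, seed=int(seed) + 7919 * r,
            regularization=regularization, p=p,
        )
        reports.append(res.report(scheme))
    return RepeatedCVResult(reports)


def ensemble_vs_individual(
    datasets: list[tuple[ExpressionMatrix, np.ndarray]],
    k: int = 5,
    d: int = 100,
    M: int = 30,
    seed: int = 0,
    regularization: float = 1.0,
    p: float | None = None,
) -> pd.DataFrame:
    """Ensemble vs single-projection CV accuracy over replicate datasets.

    For each (X, y) replicate, one CV run yields the M-member ensemble
    accuracy plus each member's individual accuracy. Returns a DataFrame
    with per-replicate ``ensemble_acc``, ``mean_individual_acc`` and
    ``first_individual_acc``. ``df.attrs`` carries ``wilcoxon_p`` (the
    one-sided paired test that the ensemble beats the individual mean),
    ``individual_accuracies`` (the replicates x M matrix of single-model
    accuracies) and ``pooled_individual_var`` — the variance of that full
    single-model accuracy distribution, the spread the ensemble is meant
    to shrink.
    """
    rows = []
    all_accs = []
    for i, (X, y) in enumerate(datasets):
        res = cross_validate(
            X, y, k=k, d=d, M=M, seed=int(seed) + 104729 * i,
            regularization=regularization, p=p, collect_members=True,
        )
        accs = res.member_accuracies()
        all_accs.append(accs)
        rows.append(
            {
                "replicate": i,
                "ensemble_acc": res.accuracy,
                "mean_individual_acc": float(accs.mean()),
                "first_individual_acc": float(accs[0]),
            }
        )
    df = pd.DataFrame(rows)
    diff = df["ensemble_acc"] - df["mean_individual_acc"]
    if np.allclose(diff, 0):
        pval = 1.0
    else:
        pval = float(wilcoxon(df["ensemble_acc"], df["mean_individual_acc"], alternative="greater").pvalue)
    df.attrs["wilcoxon_p"] = pval
    acc_matrix = np.vstack(all_accs)
    df.attrs["individual_accuracies"] = acc_matrix
    df.attrs["pooled_individual_var"] = float(acc_matrix.ravel().var(ddof=1))
    return df
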
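"""Ensemble of linear SVMs over independent sparse random projections.

Each of the M ensemble members draws its own projection matrix (seeded
``seed + m`` so every member is independently reproducible), projects the
log2(TPM+1) training matrix to d dimensions, and fits a linear-kernel SVM
with calibrated per-class probability outputs. The ensemble score for a
sample is the plain average of the members' probability vectors; the
predicted subtype is the argmax, with ties broken by class order.

Model archives are zip containers holding a JSON manifest (format
version, hyperparameters, seeds, class order, training gene list), each
member's projection in sparse triplet form, and the pickled calibrated
classifiers.
"""

from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import softmax
from sklearn.svm import SVC

from .matrix import ExpressionMatrix, Unit
from .preprocess import align_to_genes, to_log2tpm
from .projection import ProjectionMatrix, make_rp_matrix, project


def _fit_calibrated_svc(A: np.ndarray, y: np.ndarray, C: float, seed: int,
                        class_weight=None) -> SVC:
    """Linear SVM with libsvm's built-in Platt/pairwise-coupling calibration.

    libsvm's probability machinery tolerates the tiny classes common in
    subtype cohorts (its internal folds degrade gracefully instead of
    erroring), which is why it is used rather than an external
    calibration wrapper.
    """
    clf = SVC(
        kernel="linear",
        C=C,
        probability=True,
        class_weight=class_weight,
        random_state=seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        clf.fit(A, y)
    return clf

__all__ = [
    "EnsembleMember",
    "EnsembleModel",
    "PredictionResult",
    "ModelFormatError",
    "fit_ensemble",
    "predict_proba",
    "member_probabilities",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


class ModelFormatError(RuntimeError):
    """Raised when a model archive is corrupted or of an unknown version."""


@dataclass
class EnsembleMember:
    projection: ProjectionMatrix
    classifier: SVC = field(repr=False)

    def probabilities(self, X_values: np.ndarray) -> np.ndarray:
        """N x C calibrated probabilities for aligned log2tpm values (D x N)."""
        A = project(self.projection, X_values).values
        return self.classifier.predict_proba(A.T)

    def margins(self, X_values: np.ndarray) -> np.ndarray:
        A = project(self.projection, X_values).values
        dec = self.classifier.decision_function(A.T)
        if dec.ndim == 1:  # binary: expand to two columns
            dec = np.column_stack([-dec, dec])
        return dec


@dataclass
class EnsembleModel:
    members: list[EnsembleMember] = field(repr=False)
    class_order: list[str]
    train_gene_ids: list[str] = field(repr=False)
    hyperparams: dict

    @property
    def M(self) -> int:
        return len(self.members)


@dataclass
class PredictionResult:
    """Ensemble scores (N x C, rows sum to 1), argmax labels and confidences."""

    scores: np.ndarray
    labels: list[str]
    confidence: np.ndarray
    class_order: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids else list(range(len(self.labels)))
        df = pd.DataFrame(self.scores, index=idx, columns=self.class_order)
        df.insert(0, "predicted_subtype", self.labels)
        df.insert(1, "confidence", self.confidence)
        return df


def fit_ensemble(
    X: ExpressionMatrix,
    y,
    d: int = 1200,
    M: int = 30,
    seed: int = 0,
    regularization: float = 1.0,
    p: float | None = None,
    class_weight: str | dict | None = None,
) -> EnsembleModel:
    """Fit M linear SVMs on M independent d-dimensional projections of X.

    ``X`` must be in log2(TPM+1); ``y`` is a label per sample (array-like
    of length N, or a Series indexed by sample id). Every class needs at
    least two training samples. ``seed`` controls both the projection
    draws (member m uses ``seed + m``) and the probability-calibration
    folds, so a fit is fully reproducible.
    """
    if X.unit is not Unit.LOG2TPM:
        raise ValueError(f"fit_ensemble requires log2tpm input, got {X.unit.value}")
    if isinstance(y, pd.Series):
        y = y.reindex(X.sample_ids).to_numpy()
        if pd.isna(y).any():
            raise ValueError("labels missing for some samples")
    y = np.asarray(y, dtype=object)
    if len(y) != X.n_samples:
        raise ValueError(f"{len(y)} labels for {X.n_samples} samples")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with < 2 training samples: {list(small)}")
    if not 1 <= d < X.n_genes:
        raise ValueError(f"need 1 <= d < D, got d={d}, D={X.n_genes}")
    if M < 1:
        raise ValueError("ensemble size M must be >= 1")

    y = y.astype(str)
    members: list[EnsembleMember] = []
    for m in range(1, M + 1):
        member_seed = int(seed) + m
        R = make_rp_matrix(X.n_genes, d, p=p, seed=member_seed)
        A = project(R, X).values
        clf = _fit_calibrated_svc(A.T, y, regularization, member_seed, class_weight)
        members.append(EnsembleMember(projection=R, classifier=clf))

    class_order = list(members[0].classifier.classes_)
    return EnsembleModel(
        members=members,
        class_order=class_order,
        train_gene_ids=list(X.gene_ids),
        hyperparams={
            "d": int(d),
            "M": int(M),
            "p": float(members[0].projection.p),
            "seed": int(seed),
            "regularization": float(regularization),
            "kernel": "linear",
        },
    )


def _prepare_values(
    model: EnsembleModel,
    X: ExpressionMatrix,
    lengths: pd.Series | None,
    fill_missing: bool,
    min_coverage: float,
) -> tuple[np.ndarray, list[str]]:
    X = to_log2tpm(X, lengths=lengths)
    X = align_to_genes(X, model.train_gene_ids, min_coverage=min_coverage, fill_missing=fill_missing)
    return X.values, list(X.sample_ids)


def member_probabilities(
    model: EnsembleModel,
    X: ExpressionMatrix,
    lengths: pd.Series | None = None,
    fill_missing: bool = False,
    min_coverage: float = 0.9,
) -> np.ndarray:
    """Per-member calibrated probabilities, shape (M, N, C)."""
    values, _ = _prepare_values(model, X, lengths, fill_missing, min_coverage)
    return np.stack([mem.probabilities(values) for mem in model.members])


def predict_proba(
    model: EnsembleModel,
    X: ExpressionMatrix,
    lengths: pd.Series | None = None,
    fill_missing: bool = False,
    min_coverage: float = 0.9,
    raw_margins: bool = False,
) -> PredictionResult:
    """Ensemble subtype scores for new samples.

    ``X`` may be in counts (requires ``lengths``), FPKM, TPM or log2tpm;
    it is converted and aligned to the training gene list. The default
    score averages the members' calibrated probabilities; with
    ``raw_margins=True`` the members' decision values are averaged and
    softmax-normalized instead.
    """
    values, sample_ids = _prepare_values(model, X, lengths, fill_missing, min_coverage)
    if raw_margins:
        avg = np.mean([mem.margins(values) for mem in model.members], axis=0)
        scores = softmax(avg, axis=1)
    else:
        scores = np.mean([mem.probabilities(values) for mem in model.members], axis=0)
    labels = [model.class_order[i] for i in np.argmax(scores, axis=1)]
    return PredictionResult(
        scores=scores,
        labels=labels,
        confidence=scores.max(axis=1),
        class_order=list(model.class_order),
        sample_ids=sample_ids,
    )


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Write a model archive (zip: manifest + sparse projections + classifiers)."""
    path = Path(path)
    manifest = {
        "format_version": FORMAT_VERSION,
        "hyperparams": model.hyperparams,
        "class_order": model.class_order,
        "train_gene_ids": model.train_gene_ids,
        "members": [
            {"d": mem.projection.d, "D": mem.projection.D, "p": mem.projection.p, "seed": mem.projection.seed}
            for mem in model.members
        ],
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        for i, mem in enumerate(model.members):
            buf = _io.BytesIO()
            sp.save_npz(buf, mem.projection.matrix.tocoo())
            zf.writestr(f"members/{i:03d}/projection.npz", buf.getvalue())
            buf = _io.BytesIO()
            joblib.dump(mem.classifier, buf)
            zf.writestr(f"members/{i:03d}/classifier.joblib", buf.getvalue())


def load_model(path: str | Path) -> EnsembleModel:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            version = manifest.get("format_version")
            if version != FORMAT_VERSION:
                raise ModelFormatError(
                    f"unsupported model format version {version!r} (expected {FORMAT_VERSION})"
                )
            members = []
            for i, spec in enumerate(manifest["members"]):
                proj = sp.load_npz(_io.BytesIO(zf.read(f"members/{i:03d}/projection.npz"))).tocsr()
                clf = joblib.load(_io.BytesIO(zf.read(f"members/{i:03d}/classifier.joblib")))
                members.append(
                    EnsembleMember(
                        projection=ProjectionMatrix(
                            matrix=proj, d=int(spec["d"]), D=int(spec["D"]),
                            p=float(spec["p"]), seed=int(spec["seed"]),
                        ),
                        classifier=clf,
                    )
                )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, EOFError) as exc:
        raise ModelFormatError(f"corrupted or invalid model archive: {path}") from exc
    return EnsembleModel(
        members=members,
        class_order=list(manifest["class_order"]),
        train_gene_ids=list(manifest["train_gene_ids"]),
        hyperparams=dict(manifest["hyperparams"]),
    )
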
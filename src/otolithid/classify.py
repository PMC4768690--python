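"""Linear discriminant analysis on otolith STFT feature vectors.

A sample x is assigned to the class k maximizing the linear discriminant
score

    delta_k(x) = x' S^-1 mu_k - (1/2) mu_k' S^-1 mu_k + log pi_k

where mu_k is the class mean, S the pooled within-class covariance
(denominator n - K) and pi_k the prior. Priors default to uniform since the
experimental designs here are balanced. With d = 32 features and a few dozen
training samples per class, a shared (pooled) covariance is the only
estimable choice; per-class covariances (quadratic DA) are out of scope.

If the pooled covariance is ill-conditioned (condition number > 1e12) and a
ridge is supplied, ``ridge * trace(S)/d * I`` is added and recorded on the
model; a singular covariance with ridge = 0 raises with the remedy named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    SingularCovarianceError,
    UnknownClassError,
)

__all__ = [
    "LabelledFeatures",
    "DAModel",
    "ConfusionMatrix",
    "EvaluationResult",
    "train_da",
    "predict_da",
    "evaluate",
    "split_indices",
]

_COND_TRIGGER = 1e12


@dataclass(frozen=True)
class LabelledFeatures:
    """Feature matrix plus species labels.

    ``classes`` is the ordered list of unique labels (first-appearance
    order), which also fixes the deterministic tie-break in prediction.
    """

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        if X.ndim != 2 or X.shape[0] != labels.shape[0]:
            raise InvalidInputError("X must be (n, d) with one label per row")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("features must be finite")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)

    @property
    def classes(self) -> list:
        return list(pd.unique(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "LabelledFeatures":
        feats = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        if not feats:
            raise InvalidInputError("no feature columns (f01, f02, ...) found")
        return cls(X=df[feats].to_numpy(dtype=float), labels=df[label_col].to_numpy())


@dataclass(frozen=True)
class DAModel:
    """Trained linear discriminant model."""

    classes: list
    means: np.ndarray  # (K, d)
    pooled_cov: np.ndarray  # (d, d), pre-inversion, possibly ridged
    pooled_cov_inv: np.ndarray  # (d, d)
    log_priors: np.ndarray  # (K,)
    ridge: float = 0.0  # regularization actually applied

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Discriminant scores delta_k(x), shape (n, K)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise InvalidInputError(
                f"feature dimension mismatch: model d={self.d}, input d={X.shape[1]}"
            )
        Sm = self.pooled_cov_inv @ self.means.T  # (d, K)
        return X @ Sm - 0.5 * np.sum(self.means.T * Sm, axis=0) + self.log_priors

    def save(self, path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "means": self.means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "log_priors": self.log_priors.tolist(),
            "ridge": self.ridge,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DAModel":
        payload = json.loads(Path(path).read_text())
        cov = np.asarray(payload["pooled_cov"], dtype=float)
        return cls(
            classes=list(payload["classes"]),
            means=np.asarray(payload["means"], dtype=float),
            pooled_cov=cov,
            pooled_cov_inv=np.linalg.inv(cov),
            log_priors=np.asarray(payload["log_priors"], dtype=float),
            ridge=float(payload["ridge"]),
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Target species (rows) versus predicted species (columns) counts."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise InvalidInputError("counts must be a square nonnegative matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy, trace over total, as a fraction."""
        return float(np.trace(self.counts)) / self.total

    @property
    def accuracy_percent(self) -> int:
        """Overall accuracy as a percentage rounded to the nearest integer."""
        return round(100.0 * self.accuracy)

    def per_class_accuracy(self) -> dict:
        row_sums = self.counts.sum(axis=1)
        diag = np.diag(self.counts)
        return {
            c: (float(diag[i]) / row_sums[i] if row_sums[i] else float("nan"))
            for i, c in enumerate(self.classes)
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def summary(self) -> str:
        lines = [self.to_dataframe().to_string(), ""]
        for c, acc in self.per_class_accuracy().items():
            lines.append(f"{c}: {100 * acc:.0f}%")
        lines.append(
            f"overall: {np.trace(self.counts)}/{self.total} "
            f"({100 * self.accuracy:.1f}%, ~{self.accuracy_percent}%)"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class EvaluationResult:
    confusion: ConfusionMatrix
    accuracy: float
    accuracy_percent: int


def train_da(data: LabelledFeatures, prior: str = "uniform", ridge: float = 0.0) -> DAModel:
    """Fit the linear discriminant model.

    Parameters
    ----------
    prior
        ``"uniform"`` (default, balanced designs) or ``"empirical"``
        (class frequencies in the training set).
    ridge
        Relative ridge strength. Applied as ``ridge * trace(S)/d * I`` only
        when the pooled covariance's condition number exceeds 1e12; the
        model records the trigger via its ``ridge`` attribute.
    """
    X, labels = data.X, data.labels
    classes = data.classes
    K = len(classes)
    n, d = X.shape
    if K < 2:
        raise InsufficientDataError("need at least 2 classes")
    if n - K < 1:
        raise InsufficientDataError("need at least n_classes + 1 samples in total")

    means = np.empty((K, d))
    scatter = np.zeros((d, d))
    counts = np.empty(K)
    for i, c in enumerate(classes):
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise InsufficientDataError(f"class {c!r} has fewer than 2 samples")
        means[i] = Xc.mean(axis=0)
        centered = Xc - means[i]
        scatter += centered.T @ centered
        counts[i] = Xc.shape[0]
    cov = scatter / (n - K)

    applied = 0.0
    cond = np.linalg.cond(cov)
    if cond > _COND_TRIGGER:
        if ridge > 0.0:
            applied = ridge * np.trace(cov) / d
            cov = cov + applied * np.eye(d)
        elif cond > 1.0 / np.finfo(float).eps:
            raise SingularCovarianceError(
                "pooled within-class covariance is singular; pass ridge > 0 "
                "to train_da to regularize it"
            )
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled within-class covariance could not be inverted; pass ridge > 0"
        ) from exc

    if prior == "uniform":
        priors = np.full(K, 1.0 / K)
    elif prior == "empirical":
        priors = counts / n
    else:
        raise InvalidInputError(f"unknown prior {prior!r}")
    return DAModel(
        classes=classes,
        means=means,
        pooled_cov=cov,
        pooled_cov_inv=cov_inv,
        log_priors=np.log(priors),
        ridge=applied,
    )


def predict_da(model: DAModel, X: np.ndarray, return_scores: bool = False):
    """Predict class labels; ties broken deterministically by class order."""
    scores = model.scores(X)
    idx = np.argmax(scores, axis=1)  # argmax returns the first maximum
    preds = np.asarray(model.classes, dtype=object)[idx]
    if return_scores:
        return preds, scores
    return preds


def evaluate(model: DAModel, test: LabelledFeatures) -> EvaluationResult:
    """Confusion matrix (rows = target, columns = predicted) and accuracy."""
    if test.X.shape[0] == 0:
        raise InvalidInputError("test set is empty")
    class_index = {c: i for i, c in enumerate(model.classes)}
    unseen = [l for l in pd.unique(test.labels) if l not in class_index]
    if unseen:
        raise UnknownClassError(f"test labels not seen in training: {unseen}")
    preds = predict_da(model, test.X)
    K = len(model.classes)
    counts = np.zeros((K, K), dtype=int)
    for true, pred in zip(test.labels, preds):
        counts[class_index[true], class_index[pred]] += 1
    cm = ConfusionMatrix(counts=counts, classes=model.classes)
    return EvaluationResult(confusion=cm, accuracy=cm.accuracy, accuracy_percent=cm.accuracy_percent)


def split_indices(n_specimens: int, n_train: int, n_test: int, seed: int | None = None):
    """Disjoint train/test specimen indices.

    With ``seed=None`` the first ``n_train`` specimens train and the next
    ``n_test`` test (the deterministic fixed split used throughout);
    with a seed the specimens are first shuffled reproducibly.
    """
    from .errors import InvalidSplitError

    if n_train + n_test > n_specimens:
        raise InvalidSplitError(
            f"n_train + n_test = {n_train + n_test} exceeds n_specimens = {n_specimens}"
        )
    idx = np.arange(n_specimens)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(idx)
    return idx[:n_train].tolist(), idx[n_train : n_train + n_test].tolist()
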
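"""Linear soft-margin SVM on selected edges, and the reported test metrics.

The classifier is the standard primal problem
``min 1/2 ||w||^2 + c Σ max(0, 1 − y_i (w·x_i + b))`` with labels mapped to
±1, solved by libsvm via scikit-learn.  Features are standardized on the
training subjects; the training mean/SD travel with the model and are
applied to test data.  Patients (label 1) are the positive class
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.svm import SVC

__all__ = [
    "SVMModel",
    "MetricsReport",
    "train_lsvm",
    "decision_scores",
    "predict",
    "confusion_metrics",
    "roc_auc",
    "hinge_objective",
]


@dataclass
class SVMModel:
    """A trained linear SVM: weights on standardized features plus bias."""

    feature_indices: np.ndarray
    weights: np.ndarray
    bias: float
    cost: float
    mean: np.ndarray
    sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_indices": self.feature_indices.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "cost": self.cost,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }


@dataclass
class MetricsReport:
    """Confusion-matrix derived test metrics (patients positive).

    ``recall`` equals sensitivity (TP / (TP + FN)); ``precision``
    (TP / (TP + FP)) is emitted alongside.  Empty denominators yield NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def recall(self) -> float:
        return self.sensitivity

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "recall": self.recall,
            "precision": self.precision,
        }


def train_lsvm(
    X: np.ndarray,
    y: np.ndarray,
    cost: float = 1.0,
    feature_indices: np.ndarray | None = None,
    tol: float = 1e-8,
) -> SVMModel:
    """Train the linear soft-margin SVM with penalty ``cost``.

    Deterministic for fixed input.  Raises when no features are provided
    or a class is missing (a fold whose upstream selection came back empty
    must be recorded as failed by the caller, not trained).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, int)
    if X.shape[1] < 1:
        raise ValueError("no features selected; refusing to train")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    if cost <= 0:
        raise ValueError("cost must be positive")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    svc = SVC(kernel="linear", C=cost, tol=tol)
    svc.fit((X - mu) / sd, y)
    return SVMModel(
        feature_indices=(
            np.asarray(feature_indices, int)
            if feature_indices is not None
            else np.arange(X.shape[1])
        ),
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        cost=float(cost),
        mean=mu,
        sd=sd,
    )


def decision_scores(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Signed decision values ``w·x_std + b``; class 1 iff score > 0."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.weights.shape[0]}, "
            f"input has {X.shape[1]}"
        )
    return ((X - model.mean) / model.sd) @ model.weights + model.bias


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    return (decision_scores(model, X) > 0).astype(int)


def hinge_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, cost: float
) -> float:
    """Primal soft-margin objective at (w, b) on ±1-mapped labels."""
    w = np.asarray(w, float)
    s = np.where(np.asarray(y, int) == 1, 1.0, -1.0)
    margins = 1.0 - s * (np.asarray(X, float) @ w + b)
    return 0.5 * float(w @ w) + cost * float(np.clip(margins, 0.0, None).sum())


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Confusion counts and derived rates, patients (label 1) positive."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return MetricsReport(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(
    scores: np.ndarray, y_true: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """AUC (Mann–Whitney, ties counted 1/2) and the full ROC curve.

    Returns ``(auc, fpr, tpr, thresholds)`` with a curve point at every
    distinct score threshold; trapezoidal integration of the curve equals
    the rank-based AUC.
    """
    scores = np.asarray(scores, float)
    y_true = np.asarray(y_true, int)
    n1 = int(np.sum(y_true == 1))
    n0 = int(np.sum(y_true == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC")
    ranks = stats.rankdata(scores)
    auc = (ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = _roc_curve(y_true, scores, drop_intermediate=False)
    return float(auc), fpr, tpr, thresholds
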
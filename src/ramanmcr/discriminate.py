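"""Statistical discrimination of cell groups from their Raman spectra.

NIPALS-PCA on mean-centered per-cell spectra, two-class LDA on the first
four PC scores with equal priors, and a linear nu-SVM with stratified
10-fold cross-validation.  Metrics follow the clinical convention:
accuracy, sensitivity and specificity in percent, with an integer display
that truncates toward zero (29/30 -> 96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedMetricError, ValidationError
from .io import HyperspectralDataset

__all__ = [
    "PCAResult",
    "ConfusionMatrix",
    "LDAModel",
    "SVMResult",
    "nipals_pca",
    "lda_fit",
    "lda_predict",
    "svm_fit_cv",
    "confusion_metrics",
]


# ----------------------------------------------------------------- PCA


@dataclass
class PCAResult:
    loadings: np.ndarray            # m x p, orthonormal columns
    scores: np.ndarray              # n x p
    explained_fraction: np.ndarray  # per-PC fraction of total variance
    mean: np.ndarray                # feature mean removed before fitting

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])


def _cellwise_matrix(data) -> np.ndarray:
    """Samples-in-rows matrix: dataset columns (cells) become rows."""
    if isinstance(data, HyperspectralDataset):
        return data.A.T.copy()
    return np.asarray(data, dtype=float).copy()


def nipals_pca(data, p: int, tol: float = 1e-12, max_iter: int = 1000) -> PCAResult:
    """Sequential NIPALS extraction of ``p`` principal components.

    The matrix is column-mean-centered; each component is found by power
    iteration of the score/loading pair, then deflated.  Loadings are
    unit norm; the explained fraction is score variance over total
    centered variance.
    """
    X = _cellwise_matrix(data)
    n, m = X.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 samples")
    if p > min(m, n - 1):
        raise ParameterError(f"p = {p} exceeds min(m, n-1) = {min(m, n - 1)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc**2))
    if total_var == 0:
        raise ParameterError("matrix has zero variance after centering")

    loadings = np.empty((m, p))
    scores = np.empty((n, p))
    explained = np.empty(p)
    R = Xc.copy()
    for comp in range(p):
        t = R[:, int(np.argmax(np.sum(R**2, axis=0)))].copy()
        if not np.any(t):
            t = R[:, 0].copy() + 1e-12
        for _ in range(max_iter):
            v = R.T @ t / (t @ t)
            v /= np.linalg.norm(v)
            t_new = R @ v
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        loadings[:, comp] = v
        scores[:, comp] = t
        explained[comp] = float(t @ t) / total_var
        R = R - np.outer(t, v)
    return PCAResult(loadings, scores, explained, mean)


# ----------------------------------------------------------------- confusion


@dataclass
class ConfusionMatrix:
    """2x2 counts indexed (predicted, actual) over ``classes``."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or len(self.classes) != 2:
            raise ValidationError("confusion matrix must be 2x2 over two classes")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, predicted, actual, classes) -> "ConfusionMatrix":
        counts = np.zeros((2, 2), dtype=int)
        idx = {c: i for i, c in enumerate(classes)}
        for p_lab, a_lab in zip(predicted, actual):
            counts[idx[p_lab], idx[a_lab]] += 1
        return cls(counts, tuple(classes))


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float

    @property
    def display(self) -> dict:
        # integer display truncates toward zero: 29/30 = 96.7% prints as 96
        return {
            "accuracy": int(self.accuracy),
            "sensitivity": int(self.sensitivity),
            "specificity": int(self.specificity),
        }


def confusion_metrics(cm: ConfusionMatrix, positive_class) -> ClassificationMetrics:
    """Accuracy / sensitivity / specificity in percent from a 2x2 table."""
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    if positive_class not in cm.classes:
        raise ParameterError(f"{positive_class!r} is not one of {cm.classes}")
    pos = cm.classes.index(positive_class)
    neg = 1 - pos
    tp = cm.counts[pos, pos]
    tn = cm.counts[neg, neg]
    fp = cm.counts[pos, neg]
    fn = cm.counts[neg, pos]
    if tp + fn == 0:
        raise UndefinedMetricError("no actual positives: sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetricError("no actual negatives: specificity undefined")
    return ClassificationMetrics(
        accuracy=100.0 * (tp + tn) / cm.total,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
    )


# ----------------------------------------------------------------- LDA


@dataclass
class LDAModel:
    direction: np.ndarray
    threshold: float
    classes: tuple          # (negative_class, positive_class) along the direction
    ridge: float = 0.0
    discriminants: np.ndarray = field(default=None)  # training discriminant values


def lda_fit(scores: np.ndarray, labels, ridge: float = 1e-8) -> LDAModel:
    """Two-class LDA with equal priors on PC scores.

    The discriminant direction is Sw^-1 (mu1 - mu0) with Sw the pooled
    within-class covariance (a small ridge is added if Sw is singular);
    with equal priors the decision threshold sits at the midpoint of the
    projected class means.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ParameterError(f"LDA needs exactly 2 classes, got {classes}")
    X0 = X[labels == classes[0]]
    X1 = X[labels == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ParameterError("each class needs at least 2 samples")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (
        (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    ) / (len(X) - 2)
    used_ridge = 0.0
    try:
        w = np.linalg.solve(Sw, mu1 - mu0)
    except np.linalg.LinAlgError:
        used_ridge = ridge
        w = np.linalg.solve(Sw + ridge * np.eye(Sw.shape[0]), mu1 - mu0)
    thresh = float(w @ (mu0 + mu1) / 2.0)
    return LDAModel(w, thresh, classes, used_ridge, X @ w - thresh)


def lda_predict(model: LDAModel, scores: np.ndarray, actual=None):
    """Predicted labels (and a ConfusionMatrix when ``actual`` is given)."""
    d = np.asarray(scores, dtype=float) @ model.direction - model.threshold
    pred = np.where(d > 0, model.classes[1], model.classes[0])
    if actual is None:
        return pred
    return pred, ConfusionMatrix.from_labels(pred, actual, model.classes)


def lda_loo(scores: np.ndarray, labels) -> ConfusionMatrix:
    """Leave-one-out evaluation of the LDA model."""
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    preds = []
    for i in range(len(X)):
        keep = np.arange(len(X)) != i
        model = lda_fit(X[keep], labels[keep])
        preds.append(lda_predict(model, X[i : i + 1])[0])
    return ConfusionMatrix.from_labels(preds, labels, classes)


# ----------------------------------------------------------------- SVM


@dataclass
class SVMResult:
    training_confusion: ConfusionMatrix
    training_accuracy: float   # percent
    cv_accuracy: float         # percent, stratified k-fold
    cv_confusion: ConfusionMatrix
    nu: float
    folds: int
    seed: int


def svm_fit_cv(features, labels, nu: float = 0.5, folds: int = 10, seed: int = 0) -> SVMResult:
    """Linear nu-SVM: resubstitution confusion on the full data plus
    stratified k-fold cross-validated accuracy (fold layout fixed by
    ``seed``)."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import NuSVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(set(y.tolist())))
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    try:
        model = NuSVC(nu=nu, kernel="linear").fit(X, y)
    except ValueError as exc:
        raise ParameterError(
            f"nu = {nu} is infeasible for this class balance: {exc}"
        ) from exc
    train_pred = model.predict(X)
    train_cm = ConfusionMatrix.from_labels(train_pred, y, classes)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_pred = np.empty(len(y), dtype=object)
    for tr, te in skf.split(X, y):
        fold_model = NuSVC(nu=nu, kernel="linear").fit(X[tr], y[tr])
        cv_pred[te] = fold_model.predict(X[te])
    cv_cm = ConfusionMatrix.from_labels(cv_pred, y, classes)
    return SVMResult(
        training_confusion=train_cm,
        training_accuracy=100.0 * np.mean(train_pred == y),
        cv_accuracy=100.0 * np.mean(cv_pred == y),
        cv_confusion=cv_cm,
        nu=nu,
        folds=folds,
        seed=seed,
    )
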
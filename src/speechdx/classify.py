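"""Leave-one-subject-out logistic-regression evaluation of the indices.

Each pairwise diagnosis (PSP vs MSA, PD vs MSA, PD vs PSP) is evaluated
by binary logistic regression with leave-one-speaker-out (LOSO)
cross-validation: for every subject, the model is fit by maximum
likelihood on the remaining subjects and the held-out probability of the
positive class is recorded.  Pooled held-out probabilities give the ROC
AUC; thresholding them at 0.5 gives accuracy, sensitivity (recall on the
positive label) and specificity.  Positive-label conventions follow the
clinical question: PSP is positive against MSA, and the atypical
syndrome (PSP or MSA) is positive against PD.

Training folds at these sample sizes can be perfectly separable, where
the unpenalised likelihood has no maximiser; such folds are refit with a
tiny ridge penalty (lambda = 1e-4) and the event is logged.  A full-data
fit provides the decision-boundary coefficients used for the
two-dimensional index scatter plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import ValidationError

log = logging.getLogger(__name__)

#: ridge strength used when a training fold is perfectly separated
SEPARATION_RIDGE = 1e-4

POSITIVE_LABELS = {
    ("PSP", "MSA"): "PSP",
    ("PD", "MSA"): "MSA",
    ("PD", "PSP"): "PSP",
}


@dataclass
class ClassificationReport:
    """LOSO evaluation summary for one contrast and predictor set."""

    contrast: tuple[str, str]
    positive_label: str
    predictors: tuple[str, ...]
    subjects: tuple[str, ...]
    y_true: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)  # held-out P(positive)
    auc: float = 0.0
    auc_full_fit: float = 0.0
    accuracy: float = 0.0  # percent
    sensitivity: float = 0.0  # percent
    specificity: float = 0.0  # percent
    confusion: dict[str, int] = field(default_factory=dict)
    boundary: dict[str, float] = field(default_factory=dict)
    separated_folds: int = 0
    # ROC-optimal (Youden J) operating point on the pooled LOSO probabilities,
    # reported alongside the fixed 0.5 threshold
    youden_threshold: float = 0.5
    youden_sensitivity: float = 0.0  # percent
    youden_specificity: float = 0.0  # percent

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.contrast),
            "positive_label": self.positive_label,
            "predictors": list(self.predictors),
            "auc": self.auc,
            "auc_full_fit": self.auc_full_fit,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": dict(self.confusion),
            "boundary": dict(self.boundary),
            "separated_folds": self.separated_folds,
            "youden_threshold": self.youden_threshold,
            "youden_sensitivity": self.youden_sensitivity,
            "youden_specificity": self.youden_specificity,
        }

    def per_subject_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subjects,
                "true_positive_class": self.y_true.astype(int),
                "probability": self.probabilities,
            }
        )


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[LogisticRegression, bool]:
    """Maximum-likelihood fit; fall back to a tiny ridge on separation.

    Returns ``(model, ridged)``.  Separation is flagged when the
    unpenalised optimiser fails to converge or produces exploding
    coefficients.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
            model.fit(X, y)
            if np.abs(model.coef_).max() < 1e3:
                return model, False
        except (ConvergenceWarning, ValueError, np.linalg.LinAlgError):
            pass
    model = LogisticRegression(C=1.0 / SEPARATION_RIDGE, solver="lbfgs", max_iter=2000)
    model.fit(X, y)
    return model, True


def _as_matrix(X, predictors=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        cols = tuple(predictors) if predictors else tuple(X.columns)
        return X[list(cols)].to_numpy(dtype=float), cols
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    names = tuple(predictors) if predictors else tuple(
        f"x{i}" for i in range(arr.shape[1])
    )
    return arr, names


def loso_logistic(
    X,
    y,
    positive_label: str,
    subjects=None,
    predictors=None,
) -> ClassificationReport:
    """LOSO logistic-regression evaluation of predictors against labels.

    *X* is an (n, p) matrix or DataFrame of index values; *y* holds two
    class labels.  Probabilities are of *positive_label*; classification
    threshold is 0.5.
    """
    Xm, names = _as_matrix(X, predictors)
    y = np.asarray(y)
    if not np.isfinite(Xm).all():
        raise ValidationError("predictors must be finite")
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {classes}")
    if positive_label not in classes:
        raise ValidationError(f"positive label {positive_label!r} not among {classes}")
    n = len(y)
    if n < 6:
        raise ValidationError(f"LOSO needs n >= 6 subjects, got {n}")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 3:
        raise ValidationError(f"each class needs >= 3 subjects, got {counts}")
    subjects = (
        tuple(str(s) for s in subjects)
        if subjects is not None
        else tuple(f"s{i}" for i in range(n))
    )

    y_bin = (y == positive_label).astype(int)
    probs = np.empty(n)
    separated = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model, ridged = _fit_logistic(Xm[mask], y_bin[mask])
        separated += int(ridged)
        pos_col = list(model.classes_).index(1)
        probs[i] = model.predict_proba(Xm[i : i + 1])[0, pos_col]
    if separated:
        log.info("perfect separation in %d/%d LOSO folds; ridge fallback used",
                 separated, n)

    pred = (probs >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_bin == 1)).sum())
    tn = int(((pred == 0) & (y_bin == 0)).sum())
    fp = int(((pred == 1) & (y_bin == 0)).sum())
    fn = int(((pred == 0) & (y_bin == 1)).sum())

    full_model, _ = _fit_logistic(Xm, y_bin)
    pos_col = list(full_model.classes_).index(1)
    full_probs = full_model.predict_proba(Xm)[:, pos_col]

    fpr, tpr, thresholds = roc_curve(y_bin, probs)
    j_best = int(np.argmax(tpr - fpr))

    negative = [c for c in classes if c != positive_label][0]
    report = ClassificationReport(
        contrast=(positive_label, negative),
        positive_label=positive_label,
        predictors=names,
        subjects=subjects,
        y_true=y_bin,
        probabilities=probs,
        auc=float(roc_auc_score(y_bin, probs)),
        auc_full_fit=float(roc_auc_score(y_bin, full_probs)),
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        boundary=fit_boundary(Xm, y_bin, names),
        separated_folds=separated,
        youden_threshold=float(thresholds[j_best]),
        youden_sensitivity=100.0 * float(tpr[j_best]),
        youden_specificity=100.0 * (1.0 - float(fpr[j_best])),
    )
    return report


def fit_boundary(X, y, predictors=None) -> dict[str, float]:
    """Full-data logistic fit; returns intercept and per-predictor weights.

    The probability-0.5 decision boundary is the zero set of
    ``intercept + sum_j w_j x_j``.  Rank-deficient predictor matrices
    (e.g. duplicated columns) are handled with the same tiny ridge used
    for separated folds; the event is logged.
    """
    Xm, names = _as_matrix(X, predictors)
    y = np.asarray(y)
    if len(set(y.tolist())) != 2:
        raise ValidationError("boundary fit needs exactly two classes")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(Xm)), Xm])) < Xm.shape[1] + 1:
        log.info("rank-deficient predictors; using ridge-regularised boundary fit")
        model = LogisticRegression(
            C=1.0 / SEPARATION_RIDGE, solver="lbfgs", max_iter=2000
        )
        model.fit(Xm, y)
    else:
        model, _ = _fit_logistic(Xm, y)
    out = {"intercept": float(model.intercept_[0])}
    for name, w in zip(names, model.coef_[0]):
        out[str(name)] = float(w)
    return out


def plot_boundary(report: ClassificationReport, X, y, path) -> None:
    """Scatter of a 2-D predictor space with the full-data decision line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Xm, names = _as_matrix(X, report.predictors)
    if Xm.shape[1] != 2:
        raise ValidationError("boundary plot needs exactly two predictors")
    y = np.asarray(y)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, marker in zip(sorted(set(y.tolist())), ("o", "s", "^", "d")):
        m = y == label
        ax.scatter(Xm[m, 0], Xm[m, 1], label=str(label), marker=marker, alpha=0.7)
    b = report.boundary
    w1, w2 = b[names[0]], b[names[1]]
    xs = np.linspace(Xm[:, 0].min(), Xm[:, 0].max(), 50)
    if abs(w2) > 1e-12:
        ax.plot(xs, -(b["intercept"] + w1 * xs) / w2, "k-", lw=1.5)
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
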
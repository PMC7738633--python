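"""Binary delta-class prediction from the growth-rate constant alpha.

A univariate logistic regression links alpha to the imaging subtype
(positive class = high delta, the faster-growing tumors). Because the
logistic link is monotone in alpha, the ROC over predicted probabilities
coincides with the ROC over alpha itself, so the ROC staircase, AUC, and
the accuracy-maximizing discrimination threshold are all computed directly
on alpha. Candidate thresholds are midpoints between consecutive distinct
sorted alpha values plus sentinels below/above the observed range (so the
all-one-class rules are candidates too). Leave-one-out cross-validation
refits the threshold on each training fold and pools held-out predictions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort import DeltaClass

logger = logging.getLogger(__name__)

POSITIVE_CLASS = DeltaClass.HIGH


class DegenerateLabelsError(ValueError):
    """Classification requested with only one class present."""


def _to_binary(labels) -> np.ndarray:
    """1 for high delta (positive), 0 for low delta."""
    return np.array([1 if DeltaClass.coerce(l) is DeltaClass.HIGH else 0 for l in labels])


def candidate_thresholds(alphas: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct sorted alphas, plus sentinels."""
    distinct = np.unique(alphas)
    span = max(distinct[-1] - distinct[0], abs(distinct[0]), 1.0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # adjacent floats can round the midpoint up to the upper value, which the
    # strict alpha > t rule would not separate; the lower value always does
    mids = np.where(mids < distinct[1:], mids, distinct[:-1])
    return np.concatenate([[distinct[0] - span], mids, [distinct[-1] + span]])


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted alpha -> delta-class model.

    coefficients are the logistic (intercept, slope); roc_* arrays trace the
    staircase from (0,0) to (1,1) as the threshold on alpha decreases;
    threshold is the selected discrimination cut-off (month^-1), None until
    selected.
    """

    intercept: float
    slope: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    auc: float
    threshold: float | None = None
    positive_class: DeltaClass = POSITIVE_CLASS

    def predict_proba(self, alphas) -> np.ndarray:
        """P(high delta | alpha) under the logistic model."""
        z = self.intercept + self.slope * np.asarray(alphas, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, alphas, threshold: float | None = None) -> np.ndarray:
        """1 (high) where alpha > threshold, else 0 (low)."""
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no threshold selected; call select_threshold first")
        return (np.asarray(alphas, dtype=float) > thr).astype(int)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and derived metrics at a fixed threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "mcc": self.mcc,
        }


def _roc_curve(alphas: np.ndarray, y: np.ndarray):
    """ROC staircase over alpha thresholds (descending), (0,0) -> (1,1)."""
    thresholds = candidate_thresholds(alphas)[::-1]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tpr = np.array([np.sum((alphas > t) & (y == 1)) / n_pos for t in thresholds])
    fpr = np.array([np.sum((alphas > t) & (y == 0)) / n_neg for t in thresholds])
    return fpr, tpr, thresholds


def fit_classifier(alphas, labels) -> ClassifierModel:
    """Fit the logistic model and ROC of high-vs-low delta on alpha.

    Both classes must be present. Perfect separation is allowed: the
    logistic coefficients may be large (bounded-iteration fit, warning
    suppressed), but the alpha ranking — hence ROC, AUC, threshold — is
    unaffected. AUC is the trapezoid area under the staircase.
    """
    alphas = np.asarray(alphas, dtype=float)
    y = _to_binary(labels)
    if len(alphas) != len(y):
        raise ValueError("alphas and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("both delta classes must be present")
    if len(alphas) < 4:
        raise ValueError(f"need n >= 4, got {len(alphas)}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # unpenalized fit; separation gives large finite coefficients
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        lr.fit(alphas.reshape(-1, 1), y)
    fpr, tpr, thresholds = _roc_curve(alphas, y)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassifierModel(
        intercept=float(lr.intercept_[0]),
        slope=float(lr.coef_[0, 0]),
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_thresholds=thresholds,
        auc=auc,
    )


def select_threshold(model: ClassifierModel, alphas, labels) -> float:
    """Accuracy-maximizing threshold on alpha from the ROC candidates.

    Exhaustive scan of all candidate thresholds; ties broken by larger
    Youden's J (sensitivity + specificity - 1), then by smaller threshold.
    """
    alphas = np.asarray(alphas, dtype=float)
    y = _to_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best = None
    for t in np.sort(candidate_thresholds(alphas)):
        pred = alphas > t
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        acc = (tp + tn) / len(y)
        sens = tp / n_pos if n_pos else 0.0
        spec = tn / n_neg if n_neg else 0.0
        j = sens + spec - 1.0
        key = (acc, j, -t)  # maximize accuracy, then J, then smallest t
        if best is None or key > best[0]:
            best = (key, float(t))
    return best[1]


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ClassificationReport:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    n = tp + fp + tn + fn

    def ratio(num, den):
        return num / den if den else 0.0

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        mcc=mcc,
    )


def classification_report(alphas, labels, threshold: float) -> ClassificationReport:
    """Confusion counts and metrics for the rule: high delta iff alpha > threshold.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    whenever a denominator factor vanishes (all-one-class predictions).
    """
    if not math.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    alphas = np.asarray(alphas, dtype=float)
    y = _to_binary(labels)
    pred = (alphas > threshold).astype(int)
    return _report_from_predictions(y, pred)


def ccd(alphas):
    """Complementary cumulative distribution of alpha: t -> P(alpha > t).

    Returns a right-continuous step function (vectorized); 1 below the
    sample minimum, 0 at/above the maximum.
    """
    x = np.sort(np.asarray(alphas, dtype=float))
    if len(x) == 0:
        raise ValueError("need a non-empty sample")
    n = len(x)

    def fn(t):
        t = np.asarray(t, dtype=float)
        out = 1.0 - np.searchsorted(x, t, side="right") / n
        return float(out) if out.ndim == 0 else out

    return fn


@dataclass(frozen=True)
class LoocvResult:
    """Pooled leave-one-out result: held-out predictions scored together,
    per-iteration training-fold AUC summarized as mean +/- sd."""

    pooled: ClassificationReport
    auc_mean: float
    auc_sd: float
    n_iterations: int
    n_excluded: int
    per_fold_thresholds: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "pooled": self.pooled.as_dict(),
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "n_iterations": self.n_iterations,
            "n_excluded_iterations": self.n_excluded,
        }


def loocv(alphas, labels) -> LoocvResult:
    """Leave-one-out cross-validation of the threshold classifier.

    Each of n iterations drops one point, refits the classifier and
    threshold on the remaining n-1, and classifies the held-out point; the
    pooled held-out predictions are scored as one confusion matrix. A fold
    whose training set loses one class entirely is excluded with a warning.
    """
    alphas = np.asarray(alphas, dtype=float)
    y = _to_binary(labels)
    n = len(alphas)
    if n < 5:
        raise ValueError(f"need n >= 5 for LOOCV, got {n}")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("both delta classes must be present")

    held_true, held_pred, fold_aucs, fold_thresholds = [], [], [], []
    n_excluded = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            n_excluded += 1
            logger.warning("LOOCV fold %d excluded: training set lost a class", i)
            continue
        a_train = alphas[mask]
        model = fit_classifier(a_train, np.where(y_train == 1, "high", "low"))
        thr = select_threshold(model, a_train, np.where(y_train == 1, "high", "low"))
        fold_aucs.append(model.auc)
        fold_thresholds.append(thr)
        held_true.append(y[i])
        held_pred.append(1 if alphas[i] > thr else 0)

    pooled = _report_from_predictions(np.array(held_true), np.array(held_pred))
    return LoocvResult(
        pooled=pooled,
        auc_mean=float(np.mean(fold_aucs)),
        auc_sd=float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        n_iterations=len(fold_aucs),
        n_excluded=n_excluded,
        per_fold_thresholds=np.array(fold_thresholds),
    )
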
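"""Metrics, stratified cross-validation orchestration and model comparison.

All one-vs-rest metrics are macro-averaged with equal class weight, so on a
balanced test set macro recall equals accuracy (which is why sensitivity and
recall columns coincide in balanced-protocol reports).  Expected calibration
error uses 15 equal-width confidence bins with confidence = max predicted
probability.  Paired fold-wise comparisons use the paired t-test and the
exact-distribution Wilcoxon signed-rank test (five folds is far below any
normal-approximation regime).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .synthetic import LabeledImageSet

__all__ = [
    "FoldReport",
    "CvSummary",
    "classification_metrics",
    "run_cross_validation",
    "compare_folds",
    "roc_curves",
    "expected_calibration_error",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "f1",
    "auc_macro",
    "log_loss",
    "ece",
)


@dataclass
class FoldReport:
    fold_id: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    auc_macro: float
    log_loss: float
    ece: float
    confusion: np.ndarray

    def metric(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass
class CvSummary:
    per_fold: list[FoldReport]
    cumulative_confusion: np.ndarray
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.summary is None:
            self.summary = _aggregate(self.per_fold)

    def fold_values(self, metric: str) -> np.ndarray:
        return np.array([r.metric(metric) for r in self.per_fold])


def _aggregate(reports: list[FoldReport]) -> pd.DataFrame:
    """Mean, std and t-based 95% CI (mean +/- t_{0.975,n-1} * std / sqrt(n))."""
    n = len(reports)
    rows = {}
    tcrit = stats.t.ppf(0.975, n - 1) if n > 1 else np.nan
    for m in METRIC_NAMES:
        vals = np.array([r.metric(m) for r in reports])
        mean = vals.mean()
        std = vals.std(ddof=1) if n > 1 else 0.0
        half = tcrit * std / np.sqrt(n) if n > 1 else 0.0
        rows[m] = {
            "mean": mean,
            "std": std,
            "ci95_low": mean - half,
            "ci95_high": mean + half,
        }
    return pd.DataFrame(rows).T


def expected_calibration_error(
    y_true: np.ndarray, y_prob: np.ndarray, n_bins: int = 15
) -> float:
    """ECE over equal-width bins of the top-probability confidence."""
    conf = y_prob.max(axis=1)
    pred = y_prob.argmax(axis=1)
    correct = (pred == y_true).astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ece = 0.0
    n = len(y_true)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (conf > lo) & (conf <= hi) if b else (conf >= lo) & (conf <= hi)
        if mask.any():
            ece += mask.sum() / n * abs(correct[mask].mean() - conf[mask].mean())
    return float(ece)


def classification_metrics(y_true, y_prob, fold_id: int = 0) -> FoldReport:
    """Macro one-vs-rest metric bundle from true labels and class probabilities."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_prob.ndim != 2 or len(y_true) != len(y_prob):
        raise ValueError("y_prob must be (n_samples, n_classes) aligned with y_true")
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of y_prob must sum to 1")
    n, n_classes = y_prob.shape
    pred = y_prob.argmax(axis=1)

    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y_true, pred), 1)

    present = confusion.sum(axis=1) > 0
    absent = np.flatnonzero(~present)
    if absent.size:
        logger.warning("classes %s absent from y_true; excluded from macro averages", absent)

    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    tn = n - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        recall_c = tp / (tp + fn)
        spec_c = tn / (tn + fp)
        prec_c = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f1_c = np.where(prec_c + recall_c > 0, 2 * prec_c * recall_c / (prec_c + recall_c), 0.0)

    recall = float(np.nanmean(recall_c[present]))
    specificity = float(np.nanmean(spec_c[present]))
    precision = float(np.mean(prec_c[present]))
    f1 = float(np.mean(f1_c[present]))

    aucs = []
    for c in np.flatnonzero(present):
        binary = (y_true == c).astype(int)
        if 0 < binary.sum() < n:
            aucs.append(roc_auc_score(binary, y_prob[:, c]))
    auc_macro = float(np.mean(aucs)) if aucs else float("nan")

    ll = float(-np.log(np.maximum(y_prob[np.arange(n), y_true], 1e-12)).mean())
    return FoldReport(
        fold_id=fold_id,
        accuracy=float((pred == y_true).mean()),
        sensitivity=recall,
        specificity=specificity,
        precision=precision,
        recall=recall,
        f1=f1,
        auc_macro=auc_macro,
        log_loss=ll,
        ece=expected_calibration_error(y_true, y_prob),
        confusion=confusion,
    )


def run_cross_validation(
    dataset: LabeledImageSet,
    fit_predict,
    n_splits: int = 5,
    seed: int = 42,
) -> CvSummary:
    """Stratified K-fold evaluation of an arbitrary pipeline.

    ``fit_predict(train_set, test_set, fold_id)`` must train on the first
    split and return a ``(n_test, n_classes)`` probability matrix for the
    second.  Fold assignment is deterministic under the seed; the cumulative
    confusion matrix is the element-wise sum over folds.
    """
    counts = np.bincount(dataset.labels, minlength=dataset.n_classes)
    if np.any(counts[counts > 0] < n_splits):
        raise ValueError(f"every represented class needs >= {n_splits} samples")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed))
    reports = []
    cumulative = np.zeros((dataset.n_classes, dataset.n_classes), dtype=np.int64)
    for fold_id, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(dataset)), dataset.labels)
    ):
        train_split = dataset.subset(train_idx)
        test_split = dataset.subset(test_idx)
        y_prob = np.asarray(fit_predict(train_split, test_split, fold_id))
        report = classification_metrics(test_split.labels, y_prob, fold_id=fold_id)
        reports.append(report)
        cumulative += report.confusion
    return CvSummary(per_fold=reports, cumulative_confusion=cumulative)


def compare_folds(a: CvSummary, b: CvSummary, metric: str) -> tuple[float, float]:
    """Paired two-sided t-test and exact Wilcoxon signed-rank p-values on the
    fold-wise values of ``metric``; (1.0, 1.0) when all differences vanish."""
    va, vb = a.fold_values(metric), b.fold_values(metric)
    if len(va) != len(vb):
        raise ValueError("fold-count mismatch between summaries")
    diff = va - vb
    if np.allclose(diff, 0.0):
        return 1.0, 1.0
    t_p = float(stats.ttest_rel(va, vb).pvalue)
    w_p = float(stats.wilcoxon(va, vb, alternative="two-sided", method="exact").pvalue)
    return t_p, w_p


def roc_curves(y_true, y_prob):
    """One-vs-rest ROC curve per class plus the macro AUC.

    Returns ``(curves, macro_auc)`` where ``curves[c] = (fpr, tpr, auc)``.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC analysis needs at least two classes in y_true")
    curves = {}
    aucs = []
    for c in range(y_prob.shape[1]):
        binary = (y_true == c).astype(int)
        if 0 < binary.sum() < len(y_true):
            fpr, tpr, _ = roc_curve(binary, y_prob[:, c])
            auc = roc_auc_score(binary, y_prob[:, c])
            curves[c] = (fpr, tpr, float(auc))
            aucs.append(auc)
    return curves, float(np.mean(aucs))
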
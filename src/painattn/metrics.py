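"""Reliability metrics panel for 5-class pain intensity prediction.

Covers the discrimination metrics (confusion matrix, accuracy, per-class
and macro precision/recall/F1, Cohen's kappa, multiclass MCC, macro- and
micro-averaged one-vs-rest ROC AUC), the calibration metric (expected
calibration error over equal-width confidence bins) and the fold-level
statistics (t-based confidence intervals, paired t-tests).

Standard metrics delegate to scikit-learn/scipy; ECE and the calibration
bins are computed here. Conventions: macro averages are unweighted class
means; a class absent from the ground truth contributes precision/recall 0
(with a warning) and is excluded from the macro AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix as sk_confusion,
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .labels import N_CLASSES

__all__ = [
    "EvalReport", "CalibrationBins", "StatSummary",
    "confusion_and_prf", "cohens_kappa", "mcc", "ovr_auc", "ece",
    "ci_t", "paired_ttest", "evaluate",
]


def _validate_labels(y_true, y_pred, n_classes: int):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0,{n_classes})")
    return y_true, y_pred


def confusion_and_prf(y_true, y_pred, n_classes: int = N_CLASSES) -> dict:
    """Confusion matrix plus accuracy and per-class/macro P, R, F1."""
    y_true, y_pred = _validate_labels(y_true, y_pred, n_classes)
    labels = np.arange(n_classes)
    cm = sk_confusion(y_true, y_pred, labels=labels)
    if (np.bincount(y_true, minlength=n_classes) == 0).any():
        warnings.warn("some classes absent from y_true; their P/R/F1 are 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn zero-division warnings
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
    row_sums = cm.sum(axis=1, keepdims=True)
    normalized = np.divide(cm, row_sums, out=np.zeros_like(cm, dtype=float),
                           where=row_sums > 0)
    return {
        "confusion": cm,
        "confusion_normalized": normalized,
        "accuracy": float((y_true == y_pred).mean()),
        "precision": p, "recall": r, "f1": f1,
        "macro_precision": float(p.mean()),
        "macro_recall": float(r.mean()),
        "macro_f1": float(f1.mean()),
    }


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (p_o - p_e)/(1 - p_e)."""
    y_true, y_pred = _validate_labels(y_true, y_pred, N_CLASSES)
    if len(set(y_true)) == 1 and set(y_true) == set(y_pred):
        # degenerate: expected agreement is 1
        if (y_true == y_pred).all():
            return 1.0
        raise ValueError("kappa undefined: single class with imperfect agreement")
    return float(cohen_kappa_score(y_true, y_pred))


def mcc(y_true, y_pred) -> float:
    """Multiclass Matthews correlation; 0 (with warning) when undefined."""
    y_true, y_pred = _validate_labels(y_true, y_pred, N_CLASSES)
    if len(set(y_true)) == 1 or len(set(y_pred)) == 1:
        warnings.warn("MCC denominator is zero; returning 0")
        return 0.0
    return float(matthews_corrcoef(y_true, y_pred))


def ovr_auc(y_true, scores, n_classes: int = N_CLASSES) -> tuple[float, float]:
    """Macro and micro one-vs-rest ROC AUC from an (n, K) score matrix.

    Ties are handled by the rank midpoint convention. Classes absent from
    ``y_true`` are excluded from the macro average with a warning; the
    micro AUC pools all class-sample pairs into one binary problem.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape != (y_true.size, n_classes):
        raise ValueError(f"scores must be (n,{n_classes})")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    onehot = np.zeros_like(scores)
    onehot[np.arange(y_true.size), y_true] = 1.0
    present = np.flatnonzero((onehot.sum(axis=0) > 0)
                             & (onehot.sum(axis=0) < y_true.size))
    if len(present) < n_classes:
        warnings.warn("classes absent from y_true excluded from macro AUC")
    per_class = [roc_auc_score(onehot[:, c], scores[:, c]) for c in present]
    macro = float(np.mean(per_class))
    micro = float(roc_auc_score(onehot.ravel(), scores.ravel()))
    return macro, micro


@dataclass
class CalibrationBins:
    """Equal-width confidence bins over (0, 1], right-closed."""

    edges: np.ndarray          # B+1 edges
    counts: np.ndarray         # per-bin sample counts
    mean_confidence: np.ndarray
    accuracy: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def ece(self) -> float:
        weights = self.counts / max(self.n, 1)
        gaps = np.abs(self.accuracy - self.mean_confidence)
        return float(np.sum(weights * np.where(self.counts > 0, gaps, 0.0)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "bin_low": self.edges[:-1], "bin_high": self.edges[1:],
            "count": self.counts, "mean_confidence": self.mean_confidence,
            "accuracy": self.accuracy,
        })


def ece(confidences, correct, n_bins: int = 15) -> tuple[float, CalibrationBins]:
    """Expected calibration error: sum_b (n_b/n) |acc_b - conf_b|."""
    confidences = np.asarray(confidences, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if confidences.size == 0:
        raise ValueError("ece requires at least one prediction")
    if confidences.shape != correct.shape or confidences.ndim != 1:
        raise ValueError("confidences and correct flags must align")
    if (confidences < 0).any() or (confidences > 1).any():
        raise ValueError("confidences must lie in [0,1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins on (0,1]; confidence 0 joins the first bin
    idx = np.clip(np.ceil(confidences * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    conf_sum = np.bincount(idx, weights=confidences, minlength=n_bins)
    hit_sum = np.bincount(idx, weights=correct.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_conf = np.divide(conf_sum, counts, out=np.zeros(n_bins),
                              where=counts > 0)
        acc = np.divide(hit_sum, counts, out=np.zeros(n_bins), where=counts > 0)
    bins = CalibrationBins(edges=edges, counts=counts,
                           mean_confidence=mean_conf, accuracy=acc)
    return bins.ece(), bins


@dataclass
class StatSummary:
    """Per-fold values with a two-sided t confidence interval."""

    values: np.ndarray
    mean: float
    std: float           # sample std, n-1 denominator
    n: int
    level: float
    t_quantile: float
    low: float
    high: float


def ci_t(values, level: float = 0.95) -> StatSummary:
    """Mean +- t_{(1+level)/2, n-1} * s / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least two values for a t interval")
    n = values.size
    mean = float(values.mean())
    std = float(values.std(ddof=1))
    tq = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    half = tq * std / np.sqrt(n)
    return StatSummary(values=values, mean=mean, std=std, n=n, level=level,
                       t_quantile=tq, low=mean - half, high=mean + half)


def paired_ttest(values_a, values_b) -> tuple[float, float]:
    """Paired two-sided t-test on per-fold differences.

    Zero-variance differences (including identical vectors) are an error
    rather than a NaN statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.allclose(a - b, (a - b)[0]) and np.isclose(np.std(a - b, ddof=1), 0.0):
        raise ValueError("paired t-test undefined: differences have zero variance")
    t_stat, p = stats.ttest_rel(a, b)
    return float(t_stat), float(p)


@dataclass
class EvalReport:
    """The full metric panel for one evaluated prediction set."""

    n: int
    confusion: list
    confusion_normalized: list
    accuracy: float
    precision: list
    recall: list
    f1: list
    macro_precision: float
    macro_recall: float
    macro_f1: float
    kappa: float
    mcc: float
    macro_auc: float
    micro_auc: float
    ece: float
    calibration: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        return cls(**json.loads(Path(path).read_text()))


def evaluate(y_true, proba, n_bins: int = 15) -> EvalReport:
    """Compute the whole panel from true labels and an (n, K) probability matrix."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    y_pred = proba.argmax(axis=1)
    prf = confusion_and_prf(y_true, y_pred, proba.shape[1])
    macro_auc, micro_auc = ovr_auc(y_true, proba, proba.shape[1])
    conf = proba.max(axis=1)
    ece_value, bins = ece(conf, y_pred == y_true, n_bins=n_bins)
    return EvalReport(
        n=int(y_true.size),
        confusion=prf["confusion"].tolist(),
        confusion_normalized=prf["confusion_normalized"].tolist(),
        accuracy=prf["accuracy"],
        precision=prf["precision"].tolist(),
        recall=prf["recall"].tolist(),
        f1=prf["f1"].tolist(),
        macro_precision=prf["macro_precision"],
        macro_recall=prf["macro_recall"],
        macro_f1=prf["macro_f1"],
        kappa=cohens_kappa(y_true, y_pred),
        mcc=mcc(y_true, y_pred),
        macro_auc=macro_auc,
        micro_auc=micro_auc,
        ece=ece_value,
        calibration={
            "edges": bins.edges.tolist(),
            "counts": bins.counts.tolist(),
            "mean_confidence": bins.mean_confidence.tolist(),
            "accuracy": bins.accuracy.tolist(),
        },
    )
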
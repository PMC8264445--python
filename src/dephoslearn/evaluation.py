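"""Classifier evaluation: confusion-matrix scores, ROC/AUC, stratified
k-fold cross-validation, window-size scanning and relative-change
reporting.

Conventions: accuracy, sensitivity and specificity are percents
(definitions include the x100); MCC and AUC are unitless.  Report
tables round unitless values to 2 d.p. and percent changes to 1 d.p.,
half-away-from-zero.  Degenerate denominators never crash: sensitivity
and specificity report 0 with a flag, and MCC is 0 whenever any factor
of its radicand vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


def _round_half_away(value: float, decimals: int) -> float:
    scale = 10**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, calls) -> ConfusionMatrix:
    """Tally binary labels (truth) against binary calls (predictions)."""
    labels = np.asarray(labels).astype(int)
    calls = np.asarray(calls).astype(int)
    if labels.shape != calls.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {calls.shape}")
    if labels.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(((labels == 1) & (calls == 1)).sum()),
        tn=int(((labels == 0) & (calls == 0)).sum()),
        fp=int(((labels == 0) & (calls == 1)).sum()),
        fn=int(((labels == 1) & (calls == 0)).sum()),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN) x 100."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total * 100.0


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN) x 100; 0 (flagged) when there are no positives."""
    if cm.tp + cm.fn == 0:
        sensitivity.degenerate = True  # type: ignore[attr-defined]
        return 0.0
    sensitivity.degenerate = False  # type: ignore[attr-defined]
    return cm.tp / (cm.tp + cm.fn) * 100.0


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP) x 100; 0 (flagged) when there are no negatives."""
    if cm.tn + cm.fp == 0:
        specificity.degenerate = True  # type: ignore[attr-defined]
        return 0.0
    specificity.degenerate = False  # type: ignore[attr-defined]
    return cm.tn / (cm.tn + cm.fp) * 100.0


sensitivity.degenerate = False  # type: ignore[attr-defined]
specificity.degenerate = False  # type: ignore[attr-defined]


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    factors = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if factors == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(factors)


def roc_auc(labels, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the ROC curve points (fpr, tpr).

    The AUC equals the Mann-Whitney pair statistic: the fraction of
    (positive, negative) pairs ranked correctly, ties counting one half.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    roc_auc: float
    per_fold: list[dict] | None = None
    mean_sd: dict[str, tuple[float, float]] | None = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
        }
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold
            out["mean_sd"] = {k: list(v) for k, v in (self.mean_sd or {}).items()}
        if self.flags:
            out["flags"] = self.flags
        return out


METRIC_KEYS = ("accuracy", "sensitivity", "specificity", "mcc", "roc_auc")


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report from true labels and positive-class scores."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    calls = (scores >= threshold).astype(int)
    cm = confusion(labels, calls)
    auc, _, _ = roc_auc(labels, scores)
    report = MetricsReport(
        accuracy=accuracy(cm),
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        mcc=mcc(cm),
        roc_auc=auc,
    )
    report.flags["degenerate_sensitivity"] = sensitivity.degenerate
    report.flags["degenerate_specificity"] = specificity.degenerate
    return report


def kfold_cv(X, Y_labels, model_builder, trainer, k: int = 5,
             seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation with mean +/- sample SD.

    ``model_builder(fold_seed)`` returns a fresh model; ``trainer(model,
    X_train, y_train, fold_seed)`` fits it and must leave it able to
    score via ``model.predict_proba``.  Every example validates exactly
    once; fold sizes differ by at most one per class.
    """
    X = np.asarray(X)
    y = np.asarray(Y_labels).astype(int)
    class_counts = np.bincount(y, minlength=2)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > class_counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count "
                         f"{class_counts.min()}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[dict] = []
    for fold, (tr_idx, val_idx) in enumerate(splitter.split(X, y)):
        fold_seed = (seed * 1_000_003 + fold) % (2**31)
        model = model_builder(fold_seed)
        trainer(model, X[tr_idx], y[tr_idx], fold_seed)
        scores = model.predict_proba(X[val_idx])
        rep = evaluate_predictions(y[val_idx], scores)
        fold_metrics = {key: getattr(rep, key) for key in METRIC_KEYS}
        fold_metrics["n_val"] = int(len(val_idx))
        per_fold.append(fold_metrics)

    mean_sd = {}
    for key in METRIC_KEYS:
        values = np.array([f[key] for f in per_fold], dtype=float)
        mean_sd[key] = (float(values.mean()), float(values.std(ddof=1)))
    return MetricsReport(
        accuracy=mean_sd["accuracy"][0],
        sensitivity=mean_sd["sensitivity"][0],
        specificity=mean_sd["specificity"][0],
        mcc=mean_sd["mcc"][0],
        roc_auc=mean_sd["roc_auc"][0],
        per_fold=per_fold,
        mean_sd=mean_sd,
    )


def window_scan(datasets_by_size: dict[int, tuple], model_builder, trainer,
                k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Cross-validate one model per window size; flag the best row.

    ``datasets_by_size`` maps window size -> (X, labels).  The returned
    table has one row per size with mean +/- SD per metric; the best row
    is chosen by MCC, ties broken by AUC then sensitivity.
    """
    if not datasets_by_size:
        raise ValueError("no window sizes to scan")
    rows = []
    for size in sorted(datasets_by_size):
        X, y = datasets_by_size[size]
        report = kfold_cv(X, y, model_builder, trainer, k=k, seed=seed)
        row = {"window_size": size}
        assert report.mean_sd is not None
        for key in METRIC_KEYS:
            mean, sd = report.mean_sd[key]
            row[key] = _round_half_away(mean, 2)
            row[f"{key}_sd"] = _round_half_away(sd, 2)
        rows.append(row)
    table = pd.DataFrame(rows)
    ranking = table.sort_values(
        ["mcc", "roc_auc", "sensitivity"], ascending=False, kind="stable"
    )
    table["best"] = False
    table.loc[ranking.index[0], "best"] = True
    return table


def scan_to_tsv(table: pd.DataFrame, path) -> None:
    """Serialize a window-scan table with `metric +/- SD` columns."""
    out = pd.DataFrame({"window_size": table["window_size"]})
    for key in ("mcc", "specificity", "sensitivity", "accuracy"):
        out[key] = [
            f"{m} ± {s}" for m, s in zip(table[key], table[f"{key}_sd"])
        ]
    out["roc_auc"] = table["roc_auc"]
    out["best"] = table["best"]
    out.to_csv(path, sep="\t", index=False)


def relative_change(before: float, after: float) -> float:
    """Signed percent change (after - before) / before x 100, 1 d.p."""
    if before == 0:
        raise ValueError("relative change undefined for before == 0")
    return _round_half_away((after - before) / before * 100.0, 1)
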
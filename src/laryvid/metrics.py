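"""Multiclass evaluation: confusion matrix, PRF, MCC, ROC/AUC, k-fold CV.

All metrics are derived from the confusion matrix ``C`` with rows = true
class and columns = predicted class, via the one-vs-rest reduction
``TP_c = C[c, c]``, ``FN_c = row_c - TP_c``, ``FP_c = col_c - TP_c``:

    precision_c = TP_c / (TP_c + FP_c)      recall_c = TP_c / (TP_c + FN_c)
    F1_c = 2 P_c R_c / (P_c + R_c)          accuracy = trace(C) / total

(The study this pipeline follows prints the precision and recall formulas
with their denominators transposed; the standard definitions above are
what its result tables actually report, and what is implemented here.)

MCC uses the multiclass generalization over the full matrix,

    MCC = (s.c - p.t) / sqrt((s^2 - p.p)(s^2 - t.t))

with s = total, c = trace, p = column sums, t = row sums; for a 2x2 matrix
this reduces exactly to the familiar binary form
(TP.TN - FP.FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Zero denominators yield 0 with a warning (degenerate folds or classes
never predicted). AUC is the one-vs-rest rank (Mann-Whitney) statistic
with midranks for ties. Cross-validation aggregates per-fold reports as
mean +/- sample standard deviation per class and metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix",
    "per_class_prf",
    "mcc",
    "roc_auc_ovr",
    "roc_curve_points",
    "metric_report",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts grid, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(self.class_names) != c.shape[0]:
            raise ValueError("class_names length must match matrix size")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``c``."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum()) - tp
        fp = int(self.counts[:, c].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        names = list(self.class_names)
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(
    y_true, y_pred, n_classes: int, class_names: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count matrix: ``counts[i, j]`` = samples with true i predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes - 1}]")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(n_classes))
    return ConfusionMatrix(counts, tuple(class_names))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator computing {what}; reporting 0")
        return 0.0
    return num / den


def per_class_prf(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest precision, recall and F1 per class, with support."""
    rows = []
    for c, name in enumerate(cm.class_names):
        tp, fp, fn, _ = cm.one_vs_rest(c)
        p = _safe_div(tp, tp + fp, f"precision[{name}]")
        r = _safe_div(tp, tp + fn, f"recall[{name}]")
        f1 = _safe_div(2 * p * r, p + r, f"F1[{name}]") if (p + r) > 0 else 0.0
        rows.append(
            dict(class_name=name, precision=p, recall=r, f1=f1, support=tp + fn)
        )
    return pd.DataFrame(rows)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient from the full confusion matrix."""
    c = cm.counts.astype(float)
    s = c.sum()
    trace = np.trace(c)
    p = c.sum(axis=0)  # predicted-class totals
    t = c.sum(axis=1)  # true-class totals
    num = trace * s - p @ t
    den = np.sqrt(s * s - p @ p) * np.sqrt(s * s - t @ t)
    if den == 0:
        warnings.warn("zero denominator computing MCC; reporting 0")
        return 0.0
    # the coefficient is bounded by [-1, 1]; guard against sqrt round-off
    return float(np.clip(num / den, -1.0, 1.0))


def roc_auc_ovr(y_true, probabilities) -> np.ndarray:
    """One-vs-rest AUC per class via the midrank Mann-Whitney statistic.

    Classes absent from ``y_true`` (or covering all of it) get NaN: their
    AUC is undefined.
    """
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or len(probs) != len(y_true):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_classes = probs.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(probs[:, c])  # midranks for ties
        aucs[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return aucs


def roc_curve_points(y_true, scores, positive_class: int) -> pd.DataFrame:
    """(fpr, tpr, threshold) points of the one-vs-rest ROC curve."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-scores, kind="stable")
    thresholds, fpr, tpr = [np.inf], [0.0], [0.0]
    tp = fp = 0
    for i, idx in enumerate(order):
        tp += int(pos[idx])
        fp += int(~pos[idx])
        last = i + 1 == len(order)
        if last or scores[order[i + 1]] != scores[idx]:
            thresholds.append(scores[idx])
            fpr.append(fp / n_neg if n_neg else 0.0)
            tpr.append(tp / n_pos if n_pos else 0.0)
    return pd.DataFrame(dict(fpr=fpr, tpr=tpr, threshold=thresholds))


@dataclass(frozen=True)
class MetricReport:
    """Per-class and macro-averaged metrics plus accuracy and MCC.

    Values are stored on the 0-1 scale; ``to_frame(scale=100)`` renders
    the 0-100 presentation.
    """

    cm: ConfusionMatrix
    per_class: pd.DataFrame
    accuracy: float
    mcc: float
    auc: np.ndarray | None = None

    @property
    def macro_precision(self) -> float:
        return float(self.per_class["precision"].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.per_class["recall"].mean())

    @property
    def macro_f1(self) -> float:
        return float(self.per_class["f1"].mean())

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        rows = []
        for i, rec in self.per_class.iterrows():
            row = dict(
                class_name=rec["class_name"],
                precision=rec["precision"] * scale,
                recall=rec["recall"] * scale,
                f1=rec["f1"] * scale,
                support=int(rec["support"]),
            )
            if self.auc is not None:
                row["auc"] = self.auc[i] * scale
            rows.append(row)
        macro = dict(
            class_name="macro_avg",
            precision=self.macro_precision * scale,
            recall=self.macro_recall * scale,
            f1=self.macro_f1 * scale,
            support=self.cm.total,
        )
        if self.auc is not None:
            macro["auc"] = float(np.nanmean(self.auc)) * scale
        rows.append(macro)
        return pd.DataFrame(rows)

    def to_text(self, scale: float = 1.0) -> str:
        body = self.to_frame(scale).to_string(index=False, float_format="%.4f")
        return (
            f"{body}\naccuracy: {self.accuracy * scale:.4f}"
            f"\nmcc: {self.mcc:.4f}"
        )


def metric_report(
    y_true, y_pred, probabilities=None, class_names: Sequence[str] | None = None,
    n_classes: int | None = None,
) -> MetricReport:
    """Full evaluation of one prediction set."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1 if len(y_true) else 0
    cm = confusion_matrix(y_true, y_pred, n_classes, class_names)
    prf = per_class_prf(cm)
    acc = _safe_div(np.trace(cm.counts), cm.total, "accuracy")
    auc = roc_auc_ovr(y_true, probabilities) if probabilities is not None else None
    return MetricReport(cm=cm, per_class=prf, accuracy=float(acc), mcc=mcc(cm), auc=auc)


def cross_validate(
    x,
    y,
    k: int,
    build_and_train: Callable,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> tuple[list[MetricReport], pd.DataFrame]:
    """Stratified k-fold evaluation with mean +/- std aggregation.

    ``build_and_train(x_train, y_train, fold_seed)`` must return a callable
    ``predict_fn(x) -> (labels, probabilities)`` (probabilities may be
    None). Fold assignment is deterministic given the seed. Returns the
    per-fold reports and a tidy aggregate frame with columns
    (class_name, metric, mean, std) using the sample standard deviation.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("dataset smaller than the number of folds")
    binc = np.bincount(y)
    if (binc[binc > 0] < k).any():
        warnings.warn(
            "some class has fewer samples than folds; stratification relaxed"
        )
    x_idx = np.arange(len(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    for fold, (tr, va) in enumerate(skf.split(x_idx, y)):
        predict_fn = build_and_train(_take(x, tr), y[tr], seed + fold)
        labels, probs = predict_fn(_take(x, va))
        reports.append(
            metric_report(
                y[va], labels, probs, class_names=class_names,
                n_classes=int(y.max()) + 1,
            )
        )

    rows = []
    names = reports[0].per_class["class_name"]
    for metric in ("precision", "recall", "f1"):
        per_fold = np.stack([r.per_class[metric].to_numpy() for r in reports])
        for ci, name in enumerate(names):
            rows.append(
                dict(
                    class_name=name,
                    metric=metric,
                    mean=float(per_fold[:, ci].mean()),
                    std=float(per_fold[:, ci].std(ddof=1)),
                )
            )
    for metric, vals in (
        ("accuracy", [r.accuracy for r in reports]),
        ("mcc", [r.mcc for r in reports]),
    ):
        vals = np.asarray(vals)
        rows.append(
            dict(
                class_name="overall",
                metric=metric,
                mean=float(vals.mean()),
                std=float(vals.std(ddof=1)),
            )
        )
    return reports, pd.DataFrame(rows)


def _take(x, idx):
    if isinstance(x, np.ndarray):
        return x[idx]
    return [x[i] for i in idx]
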
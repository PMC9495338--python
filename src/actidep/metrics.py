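"""Confusion-matrix metrics, ROC/AUC, classification reports and k-fold CV.

Conventions: the positive class is 1 (depressed).  With Cp = TP + FN truly
positive and Cn = TN + FP truly negative,

  accuracy    = (TP + TN) / (Cp + Cn)
  precision   = TP / (TP + FP)
  recall      = TP / Cp            (identical to sensitivity)
  specificity = TN / Cn
  F1          = 2 P R / (P + R)    (harmonic mean of precision and recall)

AUC is the area under the empirical ROC by trapezoidal integration, sweeping
thresholds over the distinct predicted scores with ties grouped into one
step; it equals the Mann-Whitney rank statistic P(score+ > score-) +
0.5 P(tie), which the test suite verifies by brute force.

Zero-denominator metrics return 0 with a warning by default; pass
``strict=True`` to raise instead.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts for a binary problem (positive class = 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def cp(self) -> int:
        """Truly positive: TP + FN."""
        return self.tp + self.fn

    @property
    def cn(self) -> int:
        """Truly negative: TN + FP."""
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self) -> np.ndarray:
        """2x2 array, rows = actual (neg, pos), cols = predicted (neg, pos)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def _check_binary(y, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return y.astype(np.int64)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, what: str, strict: bool) -> float:
    if den == 0:
        if strict:
            raise ZeroDivisionError(f"{what}: zero denominator")
        warnings.warn(f"{what}: zero denominator, returning 0", UserWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix, strict: bool = False) -> float:
    return _ratio(cm.tp + cm.tn, cm.cp + cm.cn, "accuracy", strict)


def precision(cm: ConfusionMatrix, strict: bool = False) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp, "precision", strict)


def recall(cm: ConfusionMatrix, strict: bool = False) -> float:
    return _ratio(cm.tp, cm.cp, "recall", strict)


def sensitivity(cm: ConfusionMatrix, strict: bool = False) -> float:
    """True-positive rate among the truly depressed; identical to recall."""
    return recall(cm, strict)


def specificity(cm: ConfusionMatrix, strict: bool = False) -> float:
    """True-negative rate among the truly healthy."""
    return _ratio(cm.tn, cm.cn, "specificity", strict)


def f1(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: false-positive rate vs sensitivity per threshold step."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    auc: float = 0.0

    def to_csv(self, path) -> None:
        lines = ["threshold,fpr,tpr"]
        for t, x, y in zip(self.thresholds, self.fpr, self.tpr):
            lines.append(f"{t!r},{x!r},{y!r}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def roc_auc(scores, y_true) -> RocCurve:
    """ROC curve and trapezoidal AUC from class-1 scores.

    Equal scores are grouped into a single threshold step, so ties contribute
    a diagonal segment whose trapezoid equals the half-credit of the rank
    statistic.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = _check_binary(y_true, "y_true")
    if scores.shape != y_true.shape:
        raise ValueError("scores and y_true must have equal length")
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_true = y_true[order]
    # indices where a tie group of equal scores ends
    distinct = np.flatnonzero(np.diff(sorted_scores)) if len(scores) > 1 else np.array([], int)
    ends = np.append(distinct, len(scores) - 1)
    tps = np.cumsum(sorted_true)[ends]
    fps = ends + 1 - tps
    tpr = np.concatenate([[0.0], tps / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fps / n_neg, [1.0]])
    thresholds = np.concatenate([[np.inf], sorted_scores[ends], [-np.inf]])
    # drop duplicate trailing point if the sweep already reached (1, 1)
    if len(fpr) > 2 and fpr[-2] == 1.0 and tpr[-2] == 1.0:
        fpr, tpr, thresholds = fpr[:-1], tpr[:-1], thresholds[:-1]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# Classification report
# ---------------------------------------------------------------------------

_CLASS_NAMES = {0: "Not Depressed", 1: "Depressed"}


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class precision/recall/F1/support with macro and weighted averages.

    Macro averages are unweighted means per label; weighted averages are
    support-weighted means.  ``render()`` prints at two decimals; the
    unrounded values stay available on the object and via ``to_dict()``.
    """

    per_class: dict[int, ClassMetrics]
    accuracy: float
    macro: ClassMetrics
    weighted: ClassMetrics

    def to_dict(self) -> dict:
        def cm_dict(m: ClassMetrics) -> dict:
            return {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "support": m.support,
            }

        return {
            "classes": {str(k): cm_dict(v) for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_avg": cm_dict(self.macro),
            "weighted_avg": cm_dict(self.weighted),
        }

    def render(self) -> str:
        rows = []
        header = f"{'':16s}{'Precision':>10s}{'Recall':>8s}{'F1-Score':>10s}{'Support':>9s}"
        rows.append(header)
        for label in sorted(self.per_class):
            m = self.per_class[label]
            rows.append(
                f"{_CLASS_NAMES.get(label, str(label)):16s}"
                f"{m.precision:>10.2f}{m.recall:>8.2f}{m.f1:>10.2f}{m.support:>9d}"
            )
        n = self.weighted.support
        rows.append(f"{'Accuracy':16s}{'':>10s}{'':>8s}{self.accuracy:>10.2f}{n:>9d}")
        for name, m in (("Macro avg", self.macro), ("Weighted avg", self.weighted)):
            rows.append(
                f"{name:16s}{m.precision:>10.2f}{m.recall:>8.2f}{m.f1:>10.2f}{m.support:>9d}"
            )
        return "\n".join(rows)


def report_from_confusion(cm: ConfusionMatrix, strict: bool = False) -> ClassificationReport:
    """Build the full report from a positive-class confusion matrix.

    Class 1 uses the matrix as-is; class 0 is scored with the roles swapped
    (each class treated in turn as positive).
    """
    views = {
        1: cm,
        0: ConfusionMatrix(tp=cm.tn, tn=cm.tp, fp=cm.fn, fn=cm.fp),
    }
    per_class: dict[int, ClassMetrics] = {}
    for label, view in views.items():
        p = precision(view, strict)
        r = recall(view, strict)
        per_class[label] = ClassMetrics(p, r, f1(p, r), support=view.cp)
    n = cm.n
    macro = ClassMetrics(
        precision=float(np.mean([m.precision for m in per_class.values()])),
        recall=float(np.mean([m.recall for m in per_class.values()])),
        f1=float(np.mean([m.f1 for m in per_class.values()])),
        support=n,
    )
    weighted = ClassMetrics(
        precision=sum(m.precision * m.support for m in per_class.values()) / n,
        recall=sum(m.recall * m.support for m in per_class.values()) / n,
        f1=sum(m.f1 * m.support for m in per_class.values()) / n,
        support=n,
    )
    return ClassificationReport(
        per_class=per_class, accuracy=accuracy(cm, strict), macro=macro, weighted=weighted
    )


def classification_report(y_true, y_pred, strict: bool = False) -> ClassificationReport:
    return report_from_confusion(confusion(y_true, y_pred), strict=strict)


_REPORT_ROW = re.compile(
    r"^(?P<name>.+?)\s+(?P<p>\d\.\d\d)\s+(?P<r>\d\.\d\d)\s+(?P<f>\d\.\d\d)\s+(?P<s>\d+)$"
)


def parse_report(text: str) -> dict[str, dict[str, float]]:
    """Parse a rendered report back into its (two-decimal) numbers."""
    out: dict[str, dict[str, float]] = {}
    for line in text.splitlines():
        m = _REPORT_ROW.match(line.strip())
        if m:
            out[m["name"].strip()] = {
                "precision": float(m["p"]),
                "recall": float(m["r"]),
                "f1": float(m["f"]),
                "support": int(m["s"]),
            }
        else:
            acc = re.match(r"^Accuracy\s+(\d\.\d\d)\s+(\d+)$", line.strip())
            if acc:
                out["Accuracy"] = {"f1": float(acc.group(1)), "support": int(acc.group(2))}
    return out


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResults:
    """Per-fold held-out accuracy and loss, with their arithmetic means."""

    accuracies: tuple[float, ...]
    losses: tuple[float, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_loss(self) -> float:
        return float(np.mean(self.losses))

    def to_dict(self) -> dict:
        return {
            "accuracies": list(self.accuracies),
            "losses": list(self.losses),
            "mean_accuracy": self.mean_accuracy,
            "mean_loss": self.mean_loss,
        }


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded partition of range(n) into k near-equal folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def kfold_cv(X, y, fit_eval, k: int = 3, seed: int = 0) -> FoldResults:
    """Train on k-1 folds, score on the held-out fold, k times.

    ``fit_eval(X_train, y_train, X_val, y_val, fold_index)`` must return
    ``(accuracy, loss)`` for the held-out part; this module only owns the
    partitioning and aggregation.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    folds = kfold_indices(len(y), k, seed)
    accs, losses = [], []
    for fi, held in enumerate(folds):
        mask = np.zeros(len(y), dtype=bool)
        mask[held] = True
        acc, loss = fit_eval(X[~mask], y[~mask], X[mask], y[mask], fi)
        accs.append(float(acc))
        losses.append(float(loss))
    return FoldResults(accuracies=tuple(accs), losses=tuple(losses))
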
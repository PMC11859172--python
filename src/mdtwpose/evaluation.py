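"""Confusion matrices and per-class classification metrics.

Per class, in a one-vs-rest reduction of the multi-class confusion
matrix:

    sensitivity = TP / (TP + FN)        (recall)
    specificity = TN / (TN + FP)
    balanced accuracy = (sensitivity + specificity) / 2

All metrics are reported in percent. Balanced accuracy corrects for the
unequal numbers of exemplars per class that arise when kinematically
similar recordings are merged into one class. Reports can additionally
be collapsed onto coarser posture groups (kneeling, squatting, chair
sitting, floor sitting, stooping, standing, walking), which converts
within-group confusions into correct predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .sequences import CLASS_ORDER, DEFAULT_GROUPING, SequenceError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "class_metrics",
    "balanced_accuracy_from_rates",
    "overall_accuracy",
    "row_percentages",
    "group_classes",
    "metrics_report",
    "metric_summary",
    "round_half_up",
    "chance_level",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: ties away from zero (73.45 -> 73.5 at 1 decimal)."""
    if math.isnan(x):
        return x
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix indexed (target class, output class)."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise SequenceError(
                f"counts must be square over {len(self.classes)} classes; got {c.shape}"
            )
        if np.any(c < 0):
            raise SequenceError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, class_id: str) -> np.ndarray:
        return self.counts[self.classes.index(class_id)]

    def ovr_counts(self, class_id: str) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FN, TN, FP) for a class."""
        i = self.classes.index(class_id)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, tn, fp


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Count matrix with rows = target class, columns = predicted class."""
    if len(true_labels) != len(predicted_labels):
        raise SequenceError("label lists must have equal length")
    known = set(class_order)
    bad = sorted((set(true_labels) | set(predicted_labels)) - known)
    if bad:
        raise SequenceError(f"labels outside the class vocabulary: {bad}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    return ConfusionMatrix(counts=counts.astype(int), classes=tuple(class_order))


def class_metrics(cm: ConfusionMatrix, class_id: str) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) in percent for one class.

    A metric whose denominator is zero (a class with no instances, or a
    degenerate one-class matrix) is reported as ``nan`` rather than 0 or
    100 -- it is undefined, not bad or perfect.
    """
    if cm.total == 0:
        raise SequenceError("empty confusion matrix")
    tp, fn, tn, fp = cm.ovr_counts(class_id)
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else float("nan")
    return sens, spec, (sens + spec) / 2.0


def balanced_accuracy_from_rates(sensitivity_pct: float, specificity_pct: float) -> float:
    """Balanced accuracy (percent) from sensitivity/specificity percentages."""
    return 0.5 * sensitivity_pct + 0.5 * specificity_pct


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correct classifications over all classifications, in percent."""
    if cm.total == 0:
        raise SequenceError("cannot compute accuracy of an empty matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def chance_level(cm_or_n_classes) -> float:
    """Chance-level accuracy in percent: 100 / number of classes."""
    n = (
        len(cm_or_n_classes.classes)
        if isinstance(cm_or_n_classes, ConfusionMatrix)
        else int(cm_or_n_classes)
    )
    return 100.0 / n


def row_percentages(cm: ConfusionMatrix, decimals: int = 1) -> dict[str, list[float]]:
    """Each row as percentages of its row total, display-rounded half-up.

    Rows with no evaluated items are omitted (absent, not zero). Raw
    ratios remain available from ``cm.counts``.
    """
    out: dict[str, list[float]] = {}
    for cls, row in zip(cm.classes, cm.counts):
        s = row.sum()
        if s == 0:
            continue
        out[cls] = [round_half_up(100.0 * v / s, decimals) for v in row]
    return out


def group_classes(
    cm: ConfusionMatrix, grouping: Mapping[str, str] = DEFAULT_GROUPING
) -> ConfusionMatrix:
    """Collapse the matrix onto posture groups.

    Rows and columns are summed within groups, so confusions between
    classes of the same group become correct predictions; the grand
    total is conserved.
    """
    missing = [c for c in cm.classes if c not in grouping]
    if missing:
        raise SequenceError(f"grouping is missing class(es): {missing}")
    groups: list[str] = []
    for c in cm.classes:  # group order follows first appearance
        g = grouping[c]
        if g not in groups:
            groups.append(g)
    idx = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    for i, ci in enumerate(cm.classes):
        for j, cj in enumerate(cm.classes):
            counts[idx[grouping[ci]], idx[grouping[cj]]] += cm.counts[i, j]
    return ConfusionMatrix(counts=counts, classes=tuple(groups))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and summary metrics for one evaluated model."""

    classes: tuple[str, ...]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    balanced_accuracy: dict[str, float]
    overall_accuracy_pct: float

    def as_rows(self) -> list[dict]:
        return [
            {
                "class": c,
                "sensitivity": self.sensitivity[c],
                "specificity": self.specificity[c],
                "balanced_accuracy": self.balanced_accuracy[c],
            }
            for c in self.classes
        ]

    def render(self, decimals: int = 1) -> str:
        lines = [f"{'class':<14}{'sens%':>8}{'spec%':>8}{'bal%':>8}"]
        for r in self.as_rows():
            lines.append(
                f"{r['class']:<14}"
                f"{round_half_up(r['sensitivity'], decimals):>8}"
                f"{round_half_up(r['specificity'], decimals):>8}"
                f"{round_half_up(r['balanced_accuracy'], decimals):>8}"
            )
        lines.append(f"overall accuracy: {round_half_up(self.overall_accuracy_pct, decimals)}%")
        return "\n".join(lines)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Full per-class metrics report for a confusion matrix."""
    sens, spec, bal = {}, {}, {}
    for c in cm.classes:
        s, p, b = class_metrics(cm, c)
        sens[c], spec[c], bal[c] = s, p, b
    return MetricsReport(
        classes=cm.classes,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=bal,
        overall_accuracy_pct=overall_accuracy(cm),
    )


def metric_summary(
    values: Mapping[str, float], exclude: Optional[set[str]] = None
) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of per-class values.

    ``values`` maps class -> metric (percent); ``exclude`` drops classes
    (e.g. walking) from the summary.
    """
    exclude = exclude or set()
    kept = [v for c, v in values.items() if c not in exclude and not math.isnan(v)]
    if not kept:
        raise SequenceError("no classes left after exclusion")
    arr = np.asarray(kept, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
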
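"""Confusion matrix and multi-class accuracy / precision / recall / F1.

All metrics derive from one-vs-rest counts per class: treating class c as
positive, TP are its diagonal counts, FN the rest of its row, FP the rest of
its column and TN everything else, so TP + TN + FP + FN equals the total for
every class.  Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2*P*R/(P+R), and the overall accuracy is the diagonal fraction
trace/total.  Divisions with a zero denominator are flagged as undefined
(None) rather than silently reported as zero.
"""

from __future__ import annotations

import dataclasses
import io as _io
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .io import LABEL_CONDITIONS

N_CLASSES = 3
CLASS_NAMES = [LABEL_CONDITIONS[i].value.capitalize() for i in range(N_CLASSES)]


@dataclasses.dataclass
class ConfusionMatrix:
    """3x3 counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Row sums: number of true samples per class."""
        return self.counts.sum(axis=1)


@dataclasses.dataclass
class ClassMetrics:
    """One-vs-rest counts and derived metrics per class, plus overall accuracy."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: list[float | None]
    recall: list[float | None]
    f1: list[float | None]
    accuracy: float


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = N_CLASSES
) -> ConfusionMatrix:
    """Tally a confusion matrix; cell (i, j) counts true i predicted j."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return ConfusionMatrix(cm)


def confusion_from_counts(
    supports: Sequence[int], correct: Sequence[int]
) -> ConfusionMatrix:
    """Build a matrix consistent with per-class supports and diagonal counts.

    Off-diagonal errors are allocated evenly across the other two classes
    (remainder to the lower class index) — a synthetic allocation, since only
    the marginals are given.  Recalls and overall accuracy depend only on the
    supports and the diagonal and are therefore exact; precisions depend on
    the allocation and are not.
    """
    supports = np.asarray(supports, dtype=np.int64)
    correct = np.asarray(correct, dtype=np.int64)
    if (correct > supports).any():
        raise ValueError("correct counts cannot exceed supports")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for i in range(N_CLASSES):
        cm[i, i] = correct[i]
        errors = int(supports[i] - correct[i])
        others = [j for j in range(N_CLASSES) if j != i]
        cm[i, others[0]] = errors - errors // 2
        cm[i, others[1]] = errors // 2
    return ConfusionMatrix(cm)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest TP/TN/FP/FN and precision/recall/F1 per class."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else float(num) / float(den)

    precision = [_ratio(tp[c], tp[c] + fp[c]) for c in range(N_CLASSES)]
    recall = [_ratio(tp[c], tp[c] + fn[c]) for c in range(N_CLASSES)]
    f1 = []
    for p, r in zip(precision, recall):
        if p is None or r is None or p + r == 0:
            f1.append(None)
        else:
            f1.append(2 * p * r / (p + r))
    return ClassMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(tp.sum()) / total,
    )


def _fmt(v: float | None) -> str:
    return "NA" if v is None else f"{round_half_up(v, 2):.2f}"


def format_report(metrics: ClassMetrics, style: str = "markdown") -> str:
    """Render per-class precision/recall/F1 rows plus an accuracy footer.

    Values are rounded half away from zero to two decimals; undefined metrics
    render as ``NA``.  ``style`` is ``markdown`` or ``csv``.
    """
    rows = [
        (CLASS_NAMES[c], _fmt(metrics.precision[c]), _fmt(metrics.recall[c]), _fmt(metrics.f1[c]))
        for c in range(N_CLASSES)
    ]
    rows.append(("Accuracy", "", "", _fmt(metrics.accuracy)))
    header = ("Diagnostic", "Precision", "Recall", "F1-Score")
    if style == "csv":
        df = pd.DataFrame(rows, columns=header)
        return df.to_csv(index=False)
    if style == "markdown":
        lines = [
            "| " + " | ".join(header) + " |",
            "|" + "|".join(["---"] * len(header)) + "|",
        ]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        return "\n".join(lines)
    raise ValueError(f"unknown style {style!r}")


def parse_report(text: str) -> dict[str, dict[str, float | None]]:
    """Read a CSV-style report back into a nested dict (round-trip check)."""
    df = pd.read_csv(_io.StringIO(text), dtype=str).fillna("")
    out: dict[str, dict[str, float | None]] = {}
    for _, row in df.iterrows():
        vals = {}
        for col in ("Precision", "Recall", "F1-Score"):
            cell = row[col]
            vals[col] = None if cell in ("", "NA") else float(cell)
        out[row["Diagnostic"]] = vals
    return out


def plot_confusion_heatmap(cm: ConfusionMatrix, path) -> None:
    """Write a confusion-matrix heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm.counts, cmap="Blues")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    ax.set_xticks(range(N_CLASSES), CLASS_NAMES, rotation=30)
    ax.set_yticks(range(N_CLASSES), CLASS_NAMES)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
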
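"""Confusion matrix and per-class one-vs-rest evaluation metrics.

For the multiclass case each class in turn is the positive and the other
classes pool into the negative, giving per-class TP/FP/TN/FN and hence

    precision = TP / (TP + FP)            recall  = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)   Jaccard = TP / (TP + FP + FN)
    accuracy  = (TP + TN) / total

All scores lie in [0, 1]; a zero denominator yields 0 with a per-class
warning flag.  Rows of the matrix are the evaluated (true) labels, columns
the predicted labels, in the fixed class order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .labels import CLASSES, FULL_NAMES, LABEL_TO_INDEX


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (N, N) non-negative ints; rows true, cols predicted
    labels: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if counts.shape != (n, n) or (counts < 0).any():
            raise DataError(f"confusion matrix must be non-negative {n}x{n}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="evaluated\\predicted")

    def plot(self, ax=None):
        """Heatmap with evaluated labels on y and predicted on x."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(self.counts, cmap="Blues")
        ax.set_xticks(range(len(self.labels)), self.labels)
        ax.set_yticks(range(len(self.labels)), self.labels)
        ax.set_xlabel("predicted label")
        ax.set_ylabel("evaluated label")
        for i in range(len(self.labels)):
            for j in range(len(self.labels)):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center", fontsize=8)
        ax.figure.colorbar(im, ax=ax)
        return ax


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionMatrix:
    """Tally counts[i][j] = number of items with true class i predicted j."""
    if len(true_labels) != len(predicted_labels):
        raise DataError(
            f"label sequences differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    n = len(CLASSES)
    counts = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in LABEL_TO_INDEX or p not in LABEL_TO_INDEX:
            raise DataError(f"unknown label in pair ({t!r}, {p!r})")
        counts[LABEL_TO_INDEX[t], LABEL_TO_INDEX[p]] += 1
    return ConfusionMatrix(counts)


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with the given class as positive."""
    n = len(cm.labels)
    if not 0 <= class_index < n:
        raise DataError(f"class index {class_index} out of range 0..{n - 1}")
    c = cm.counts
    tp = int(c[class_index, class_index])
    fp = int(c[:, class_index].sum()) - tp
    fn = int(c[class_index, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/Jaccard/support plus overall accuracy."""

    per_class: pd.DataFrame  # index: class labels
    accuracy: float
    level: str = "patch"  # which granularity was evaluated ("patch" or "image")

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        df.insert(0, "Class", [FULL_NAMES[l] for l in df.index])
        return df

    def to_csv(self, path: str | Path) -> None:
        out = self.to_frame().rename(
            columns={
                "precision": "Precision",
                "recall": "Recall",
                "f1": "F1-score",
                "jaccard": "Jaccard",
                "support": "Support",
            }
        )
        out.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "level": self.level,
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def metrics(cm: ConfusionMatrix, level: str = "patch") -> MetricsReport:
    """Per-class one-vs-rest metrics and the overall accuracy (trace/total)."""
    if cm.total == 0:
        raise DataError("cannot compute metrics of an empty confusion matrix")
    rows = {}
    for i, label in enumerate(cm.labels):
        tp, fp, tn, fn = one_vs_rest_counts(cm, i)
        precision, z1 = _safe_div(tp, tp + fp)
        recall, z2 = _safe_div(tp, tp + fn)
        f1, z3 = _safe_div(2 * tp, 2 * tp + fp + fn)
        jaccard, z4 = _safe_div(tp, tp + fp + fn)
        rows[label] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "jaccard": jaccard,
            "support": tp + fn,
            "zero_division": z1 or z2 or z3 or z4,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    accuracy = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(per_class=per_class, accuracy=accuracy, level=level)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1 scores."""
    return float(metrics(cm).per_class["f1"].mean())
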
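"""Confusion matrices, classification metrics and learning-rate sweeps.

Metrics follow the usual definitions on a rows-true / columns-predicted
count matrix: accuracy = 100·trace/total; per-class precision =
N_TP/N_PP, recall = N_TP/N_AP, f1 = harmonic mean of the two; macro
averages are unweighted means over classes.  A class never predicted (or
never present) has an undefined ratio, reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureSet
from .lstm import LstmConfig, StackedLstmClassifier

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "accuracy_from_cm",
    "precision_recall_f1",
    "accuracy_delta",
    "sweep",
]

DEFAULT_CLASSES = ("ST", "SI", "WA")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix: rows = true labels, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for classes {self.classes}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class MetricsReport:
    """Accuracy plus per-class and macro precision/recall/f1, in percent.

    ``undefined`` lists (class, metric) pairs whose denominator was zero;
    those values are reported as 0.
    """

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_tp: dict[str, int]
    n_pp: dict[str, int]
    n_ap: dict[str, int]
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self, ndigits: int = 2) -> dict:
        rnd = lambda x: round(float(x), ndigits)  # noqa: E731
        return {
            "accuracy": rnd(self.accuracy),
            "precision": {c: rnd(v) for c, v in self.precision.items()},
            "recall": {c: rnd(v) for c, v in self.recall.items()},
            "f1": {c: rnd(v) for c, v in self.f1.items()},
            "macro_precision": rnd(self.macro_precision),
            "macro_recall": rnd(self.macro_recall),
            "macro_f1": rnd(self.macro_f1),
            "n_tp": self.n_tp, "n_pp": self.n_pp, "n_ap": self.n_ap,
            "undefined": [list(u) for u in self.undefined],
        }


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     classes: Sequence[str] = DEFAULT_CLASSES) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = samples of true class i predicted j."""
    true_labels = [str(l) for l in true_labels]
    predicted_labels = [str(l) for l in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) outside classes {tuple(classes)}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def accuracy_from_cm(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent (full precision; round for display)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def precision_recall_f1(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and macro precision, recall and f1 from a count matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    n_tp: dict[str, int] = {}
    n_pp: dict[str, int] = {}
    n_ap: dict[str, int] = {}
    undefined: list[tuple[str, str]] = []
    for k, cls in enumerate(cm.classes):
        tp = int(counts[k, k])
        pp = int(counts[:, k].sum())
        ap = int(counts[k, :].sum())
        n_tp[cls], n_pp[cls], n_ap[cls] = tp, pp, ap
        if pp == 0:
            precision[cls] = 0.0
            undefined.append((cls, "precision"))
        else:
            precision[cls] = 100.0 * tp / pp
        if ap == 0:
            recall[cls] = 0.0
            undefined.append((cls, "recall"))
        else:
            recall[cls] = 100.0 * tp / ap
        p, r = precision[cls], recall[cls]
        f1[cls] = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    k = len(cm.classes)
    return MetricsReport(
        accuracy=accuracy_from_cm(cm),
        precision=precision, recall=recall, f1=f1,
        macro_precision=sum(precision.values()) / k,
        macro_recall=sum(recall.values()) / k,
        macro_f1=sum(f1.values()) / k,
        n_tp=n_tp, n_pp=n_pp, n_ap=n_ap, undefined=undefined,
    )


def accuracy_delta(cm_a: ConfusionMatrix, cm_b: ConfusionMatrix) -> float:
    """Accuracy(a) − accuracy(b) in percentage points, rounded to 2 decimals.

    Computed on unrounded accuracies and rounded last, so small
    differences are not distorted by double rounding.
    """
    return round(accuracy_from_cm(cm_a) - accuracy_from_cm(cm_b), 2)


def sweep(datasets: Mapping[str, FeatureSet], test_set: FeatureSet,
          learning_rates: Iterable[float], cfg: LstmConfig | None = None,
          seeds: Iterable[int] = (0,),
          classes: Sequence[str] = DEFAULT_CLASSES,
          ) -> tuple[pd.DataFrame, dict[tuple[str, float, int], ConfusionMatrix]]:
    """Train/evaluate every (training variant, learning rate, seed) cell.

    All variants are evaluated on the same held-out ``test_set`` —
    augmentation only ever touches training data.  Returns a tidy frame
    (variant, learning_rate, seed, accuracy, macro metrics, n_train,
    n_test) and the confusion matrix per cell.
    """
    if not datasets:
        raise ValueError("at least one training variant is required")
    rates = list(learning_rates)
    if not rates:
        raise ValueError("at least one learning rate is required")
    base = cfg or LstmConfig()
    rows = []
    matrices: dict[tuple[str, float, int], ConfusionMatrix] = {}
    for variant, train_set in datasets.items():
        for rate in rates:
            for seed in seeds:
                run_cfg = LstmConfig(**{**vars(base),
                                        "learning_rate": rate, "seed": seed})
                model = StackedLstmClassifier(run_cfg)
                model.fit(train_set.X, train_set.labels)
                pred = model.predict(test_set.X)
                cm = confusion_matrix(test_set.labels, pred, classes)
                report = precision_recall_f1(cm)
                matrices[(variant, rate, seed)] = cm
                rows.append({
                    "variant": variant, "learning_rate": rate, "seed": seed,
                    "accuracy": round(report.accuracy, 2),
                    "macro_precision": round(report.macro_precision, 2),
                    "macro_recall": round(report.macro_recall, 2),
                    "macro_f1": round(report.macro_f1, 2),
                    "n_train": len(train_set), "n_test": len(test_set),
                })
    return pd.DataFrame(rows), matrices
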
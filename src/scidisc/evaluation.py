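"""Confusion-matrix algebra and the evaluation metrics of the toolkit.

All classifier evaluation flows through a :class:`ConfusionMatrix` (rows =
gold, columns = predicted) and an :class:`EvalReport` derived from it:
per-class precision, recall and F1, and the support-weighted F1

    weighted_F1 = sum_i support_i * F1_i / sum_i support_i .

Zero denominators follow the convention precision = recall = 0 when a class
was never predicted / never occurs, and F1 = 0 when both are 0.  The
most-frequent-class baseline — predict every item as the single most common
class — has the closed form ``p * 2p/(1+p)`` with ``p`` the majority-class
share; it is the reference point every classifier in the package is
compared against.

Values are carried at full precision; :func:`round2` applies half-up
rounding to 2 decimals only at presentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Sequence

import numpy as np


def round2(x: float) -> float:
    """Half-up rounding to two decimals (presentation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # shape (L, L); rows = gold, columns = predicted

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("label list does not match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("confusion matrix counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, stream: IO) -> None:
        w = csv.writer(stream, delimiter="\t", lineterminator="\n")
        w.writerow(["", *self.labels])
        for label, row in zip(self.labels, self.counts):
            w.writerow([label, *row.tolist()])

    @classmethod
    def from_tsv(cls, stream: IO) -> "ConfusionMatrix":
        rows = [r for r in csv.reader(stream, delimiter="\t") if r and not r[0].startswith("#")]
        labels = tuple(rows[0][1:])
        counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=np.int64)
        row_labels = tuple(r[0] for r in rows[1:])
        if row_labels != labels:
            raise ValueError("row and column label order differ")
        return cls(labels, counts)


def matrix_from_predictions(
    pairs: Iterable[tuple[str, str]], label_order: Sequence[str]
) -> ConfusionMatrix:
    """Count (gold, predicted) pairs into a matrix with the given label order."""
    index = {label: i for i, label in enumerate(label_order)}
    counts = np.zeros((len(index), len(index)), dtype=np.int64)
    for gold, pred in pairs:
        if gold not in index:
            raise ValueError(f"unknown gold label {gold!r}")
        if pred not in index:
            raise ValueError(f"unknown predicted label {pred!r}")
        counts[index[gold], index[pred]] += 1
    return ConfusionMatrix(tuple(label_order), counts)


@dataclass
class LabelStats:
    label: str
    support: int
    predictions: int
    correct: int
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    per_label: list[LabelStats]
    weighted_f1: float
    total: int
    accuracy: float

    def stats(self, label: str) -> LabelStats:
        for s in self.per_label:
            if s.label == label:
                return s
        raise KeyError(label)

    def rounded(self) -> dict[str, dict[str, float]]:
        out = {
            s.label: {
                "precision": round2(s.precision),
                "recall": round2(s.recall),
                "f1": round2(s.f1),
            }
            for s in self.per_label
        }
        out["__overall__"] = {"weighted_f1": round2(self.weighted_f1),
                              "accuracy": round2(self.accuracy)}
        return out

    def to_tsv(self, stream: IO) -> None:
        w = csv.writer(stream, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "support", "predictions", "correct",
                    "precision", "recall", "f1"])
        for s in self.per_label:
            w.writerow([s.label, s.support, s.predictions, s.correct,
                        f"{round2(s.precision):.2f}", f"{round2(s.recall):.2f}",
                        f"{round2(s.f1):.2f}"])
        w.writerow(["weighted_f1", self.total, "", "", "", "",
                    f"{round2(self.weighted_f1):.2f}"])


def report_from_matrix(matrix: ConfusionMatrix) -> EvalReport:
    """Per-class precision/recall/F1 and support-weighted F1 from counts."""
    counts = matrix.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    diag = np.diag(counts)
    per_label = []
    for i, label in enumerate(matrix.labels):
        precision = diag[i] / col_sums[i] if col_sums[i] else 0.0
        recall = diag[i] / row_sums[i] if row_sums[i] else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_label.append(
            LabelStats(label, int(row_sums[i]), int(col_sums[i]), int(diag[i]),
                       float(precision), float(recall), float(f1))
        )
    total = int(counts.sum())
    if total == 0:
        weighted = 0.0
        accuracy = 0.0
    else:
        weighted = float(sum(s.support * s.f1 for s in per_label) / total)
        accuracy = float(diag.sum() / total)
    return EvalReport(per_label, weighted, total, accuracy)


def most_frequent_baseline(supports: Sequence[int]) -> float:
    """Weighted F1 of the constant most-frequent-class predictor.

    With majority share ``p = max(supports)/total`` the majority class gets
    precision ``p``, recall 1 and F1 ``2p/(1+p)``; all other classes score
    0, so the support-weighted F1 is ``p * 2p/(1+p)``.
    """
    supports = list(supports)
    if not supports or any(s < 0 for s in supports):
        raise ValueError("supports must be non-empty and non-negative")
    total = sum(supports)
    if total == 0:
        raise ValueError("total support must be positive")
    p = max(supports) / total
    return p * (2 * p / (1 + p))
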
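"""Micro/macro precision, recall, and F1 for single-label multiclass output.

With one predicted and one true label per instance, the micro-averaged
precision, recall, and F1 all collapse to plain accuracy; macro averages
are unweighted means of the per-class scores over the label set L.  A class
absent from both truth and prediction contributes 0 by default (set
``zero_support="skip"`` to drop such classes from the average instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

__all__ = [
    "PredictionSet",
    "ClassScores",
    "EvaluationReport",
    "f1",
    "micro_score",
    "macro_scores",
    "per_class_scores",
    "evaluate",
]


@dataclass(frozen=True)
class PredictionSet:
    """Aligned true/predicted labels over a shared label set L."""

    instance_ids: tuple[Hashable, ...]
    y_true: tuple[Hashable, ...]
    y_pred: tuple[Hashable, ...]
    labels: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        if not (len(self.instance_ids) == len(self.y_true) == len(self.y_pred)):
            raise ValueError("ids, y_true and y_pred must have equal length")

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[Hashable],
        y_pred: Sequence[Hashable],
        labels: Sequence[Hashable] | None = None,
    ) -> "PredictionSet":
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred), key=str)
        return cls(
            tuple(range(len(y_true))), tuple(y_true), tuple(y_pred), tuple(labels)
        )


@dataclass(frozen=True)
class ClassScores:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class EvaluationReport:
    micro: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[Hashable, ClassScores] = field(default_factory=dict)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); defined as 0 when P = R = 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def micro_score(preds: PredictionSet) -> float:
    """Micro precision = recall = F1 = fraction of exact label matches."""
    if not preds.y_true:
        raise ValueError("cannot score an empty prediction set")
    hits = sum(t == p for t, p in zip(preds.y_true, preds.y_pred))
    return hits / len(preds.y_true)


def per_class_scores(preds: PredictionSet) -> dict[Hashable, ClassScores]:
    out: dict[Hashable, ClassScores] = {}
    for label in preds.labels:
        tp = sum(t == label and p == label for t, p in zip(preds.y_true, preds.y_pred))
        pred_n = sum(p == label for p in preds.y_pred)
        true_n = sum(t == label for t in preds.y_true)
        precision = tp / pred_n if pred_n else 0.0
        recall = tp / true_n if true_n else 0.0
        out[label] = ClassScores(precision, recall, f1(precision, recall), true_n)
    return out


def macro_scores(
    preds: PredictionSet, zero_support: str = "zero"
) -> tuple[float, float, float]:
    """Unweighted per-class means of (precision, recall, F1) over L.

    ``zero_support="zero"`` counts classes absent from both truth and
    prediction as 0 in each average; ``"skip"`` drops them.
    """
    if not preds.y_true:
        raise ValueError("cannot score an empty prediction set")
    if zero_support not in ("zero", "skip"):
        raise ValueError("zero_support must be 'zero' or 'skip'")
    scores = per_class_scores(preds)
    if zero_support == "skip":
        active = [
            label
            for label in preds.labels
            if scores[label].support > 0 or any(p == label for p in preds.y_pred)
        ]
    else:
        active = list(preds.labels)
    if not active:
        raise ValueError("no classes to average over")
    n = len(active)
    return (
        sum(scores[c].precision for c in active) / n,
        sum(scores[c].recall for c in active) / n,
        sum(scores[c].f1 for c in active) / n,
    )


def evaluate(preds: PredictionSet, zero_support: str = "zero") -> EvaluationReport:
    mp, mr, mf = macro_scores(preds, zero_support=zero_support)
    return EvaluationReport(
        micro=micro_score(preds),
        macro_precision=mp,
        macro_recall=mr,
        macro_f1=mf,
        per_class=per_class_scores(preds),
    )
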
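"""Inter-annotator agreement: simple index, Cohen's kappa, G-index.

For two annotators labelling the same N units with k categories, let P0 be
the observed proportion of agreement (the simple index), Pe the chance
agreement implied by the two annotators' marginals, and Pk = 1/k the chance
level of a uniform k-category annotator.  Then

    kappa  = 1 - (1 - P0) / (1 - Pe)
    G      = 1 - (1 - P0) / (1 - Pk)

kappa corrects for each annotator's empirical label distribution; the
G-index corrects only for the number of categories, making it robust when
marginals are heavily skewed.  Entity and trigger spans are additionally
compared with strict (identical span and type) or soft (overlapping span,
same type) matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .standoff import EntityAnnotation, TriggerAnnotation

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "simple_index",
    "expected_agreement",
    "cohen_kappa",
    "g_index",
    "agreement_report",
    "span_agreement",
    "relation_label_pairs",
]


class DegenerateAgreementError(ValueError):
    """Metric undefined for this matrix (N = 0 or a single category)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k count matrix; rows index annotator 2, columns annotator 1."""

    categories: tuple[Hashable, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.categories)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.categories)

    @classmethod
    def from_label_pairs(
        cls,
        pairs: Sequence[tuple[Hashable, Hashable]],
        categories: Sequence[Hashable] | None = None,
    ) -> "ConfusionMatrix":
        """Build from (annotator1 label, annotator2 label) pairs."""
        if categories is None:
            categories = sorted({a for a, _ in pairs} | {b for _, b in pairs}, key=str)
        cats = tuple(categories)
        idx = {c: i for i, c in enumerate(cats)}
        counts = np.zeros((len(cats), len(cats)), dtype=np.int64)
        for a1, a2 in pairs:
            counts[idx[a2], idx[a1]] += 1
        return cls(cats, counts)


@dataclass(frozen=True)
class AgreementReport:
    simple_index: float  # P0
    expected_agreement: float  # Pe
    chance_level: float  # Pk = 1/k
    kappa: float | None  # None when Pe = 1 (degenerate)
    g_index: float


def simple_index(cm: ConfusionMatrix) -> float:
    """Observed agreement P0 = trace / N."""
    if cm.N == 0:
        raise DegenerateAgreementError("simple index undefined for N = 0")
    return float(np.trace(cm.counts)) / cm.N


def expected_agreement(cm: ConfusionMatrix) -> float:
    """Chance agreement Pe = (1/N^2) * sum_k n_k1 * n_k2.

    n_k1 is annotator 1's marginal for category k (column sums) and n_k2
    annotator 2's (row sums).
    """
    if cm.N == 0:
        raise DegenerateAgreementError("expected agreement undefined for N = 0")
    n1 = cm.counts.sum(axis=0).astype(float)  # annotator 1 marginals
    n2 = cm.counts.sum(axis=1).astype(float)  # annotator 2 marginals
    return float((n1 * n2).sum()) / cm.N**2


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """kappa = 1 - (1 - P0)/(1 - Pe); undefined when Pe = 1."""
    p0 = simple_index(cm)
    pe = expected_agreement(cm)
    if pe >= 1.0:
        raise DegenerateAgreementError(
            "kappa undefined: both annotators used a single category (Pe = 1)"
        )
    return 1.0 - (1.0 - p0) / (1.0 - pe)


def g_index(p0: float, k: int) -> float:
    """G = 1 - (1 - P0)/(1 - 1/k) for k >= 2 categories."""
    if k < 2:
        raise ValueError("G-index needs at least 2 categories")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"P0 must be a proportion, got {p0}")
    return 1.0 - (1.0 - p0) / (1.0 - 1.0 / k)


def agreement_report(cm: ConfusionMatrix) -> AgreementReport:
    p0 = simple_index(cm)
    pe = expected_agreement(cm)
    kappa = None if pe >= 1.0 else 1.0 - (1.0 - p0) / (1.0 - pe)
    return AgreementReport(
        simple_index=p0,
        expected_agreement=pe,
        chance_level=1.0 / cm.k,
        kappa=kappa,
        g_index=g_index(p0, cm.k),
    )


def span_agreement(
    set_a: Sequence[EntityAnnotation | TriggerAnnotation],
    set_b: Sequence[EntityAnnotation | TriggerAnnotation],
    mode: str = "strict",
) -> float:
    """Proportion of span units the two annotators matched.

    strict: identical (span, type); soft: overlapping spans of the same type.
    Units are paired greedily left-to-right, each at most once, and the
    denominator is max(|A|, |B|).  Two empty sets agree perfectly.
    """
    if mode not in ("strict", "soft"):
        raise ValueError(f"mode must be 'strict' or 'soft', got {mode!r}")
    if not set_a and not set_b:
        return 1.0
    a_sorted = sorted(set_a, key=lambda u: u.span)
    b_sorted = sorted(set_b, key=lambda u: u.span)
    used = [False] * len(b_sorted)
    matched = 0
    for ua in a_sorted:
        for j, ub in enumerate(b_sorted):
            if used[j]:
                continue
            if _unit_type(ua) != _unit_type(ub):
                continue
            hit = ua.span == ub.span if mode == "strict" else ua.span.overlaps(ub.span)
            if hit:
                used[j] = True
                matched += 1
                break
    return matched / max(len(set_a), len(set_b))


def _unit_type(u: EntityAnnotation | TriggerAnnotation) -> str:
    return u.etype if isinstance(u, EntityAnnotation) else u.rtype


def relation_label_pairs(doc_a, doc_b) -> list[tuple[str, str]]:
    """Pair relation labels of two annotations of the same document.

    Relations are keyed by the (plant span, disease span) of their argument
    entities; only pairs labelled by both annotators contribute.
    """
    def keyed(doc):
        ents = doc.entity_by_id()
        return {
            (ents[r.plant_id].span, ents[r.disease_id].span): r.rtype
            for r in doc.relations
        }

    ka, kb = keyed(doc_a), keyed(doc_b)
    return [(ka[k], kb[k]) for k in sorted(ka.keys() & kb.keys())]
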
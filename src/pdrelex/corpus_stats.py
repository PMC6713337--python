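"""Descriptive statistics over a standoff corpus.

Covers relation-type counts split by trigger presence, normalized trigger
frequency and top-k coverage, per-concept relation rankings (mentions are
aggregated by their normalized concept id), title/abstract section
breakdowns, and the mean number of relations per abstract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .standoff import (
    POSITIVE_TYPES,
    RELATION_TYPES,
    Span,
    StandoffDocument,
)

__all__ = [
    "RelationTypeCounts",
    "ConceptRanking",
    "SectionStats",
    "relation_type_counts",
    "normalize_trigger",
    "top_k_trigger_coverage",
    "concept_frequency",
    "section_stats",
    "relations_per_abstract",
]


@dataclass(frozen=True)
class RelationTypeCounts:
    """Per-type relation counts, split by trigger presence."""

    with_trigger: dict[str, int]
    without_trigger: dict[str, int]

    def total(self, rtype: str) -> int:
        return self.with_trigger.get(rtype, 0) + self.without_trigger.get(rtype, 0)

    @property
    def positive_total(self) -> int:
        return sum(self.total(t) for t in POSITIVE_TYPES)

    @property
    def negative_total(self) -> int:
        return self.total("Negative")

    @property
    def grand_total(self) -> int:
        return self.positive_total + self.negative_total


@dataclass(frozen=True)
class ConceptRanking:
    """(name, concept id, count) triples, counts non-increasing."""

    entries: tuple[tuple[str, str, int], ...]

    def top(self, n: int) -> tuple[tuple[str, str, int], ...]:
        return self.entries[:n]

    def share(self, concept_id: str, total: int) -> float:
        """Percentage of ``total`` relations held by ``concept_id``."""
        count = next((c for _, cid, c in self.entries if cid == concept_id), 0)
        return 100.0 * count / total if total else 0.0


def relation_type_counts(corpus: Iterable[StandoffDocument]) -> RelationTypeCounts:
    with_t = {t: 0 for t in RELATION_TYPES}
    without_t = {t: 0 for t in RELATION_TYPES}
    for doc in corpus:
        for r in doc.relations:
            (with_t if r.trigger_id is not None else without_t)[r.rtype] += 1
    return RelationTypeCounts(with_t, without_t)


# ---------------------------------------------------------------------------
# trigger normalization
#
# Triggers are short verb (occasionally noun) phrases; normalization folds
# tense/number variants and trailing prepositions onto one canonical form,
# e.g. "reduced"/"reducing" -> "reduce", "associated with" -> "associate".

_PREPOSITIONS = {
    "of", "with", "against", "to", "in", "on", "for", "from", "by", "at", "upon",
}

# Small exception lexicon for this domain (covers verbs whose stem restores a
# final "e", which plain suffix stripping cannot recover); the suffix rules
# below cover the rest.
_LEMMA_EXCEPTIONS = {
    "association": "associate", "associations": "associate",
    "correlation": "correlate", "correlations": "correlate",
    "reduced": "reduce", "reducing": "reduce",
    "related": "relate", "relating": "relate",
    "induced": "induce", "inducing": "induce",
    "caused": "cause", "causing": "cause",
    "increased": "increase", "increasing": "increase",
    "decreased": "decrease", "decreasing": "decrease",
    "associated": "associate", "associating": "associate",
    "influenced": "influence", "influencing": "influence",
    "promoted": "promote", "promoting": "promote",
    "ameliorated": "ameliorate", "ameliorating": "ameliorate",
    "attenuated": "attenuate", "attenuating": "attenuate",
    "improved": "improve", "improving": "improve",
    "correlated": "correlate", "observed": "observe", "raised": "raise",
    "exacerbated": "exacerbate", "exacerbating": "exacerbate",
    "provoked": "provoke", "provoking": "provoke",
    "aggravated": "aggravate", "aggravating": "aggravate",
    "rose": "rise", "risen": "rise", "shown": "show", "showed": "show",
    "found": "find", "gave": "give", "given": "give",
}

_VOWELS = "aeiou"


def _lemmatize(word: str) -> str:
    if word in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("eed"):
        return word  # agreed-style forms left alone
    if word.endswith("ed") and len(word) > 3:
        stem = word[:-2]  # prevented -> prevent, treated -> treat
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS + "sl":
            stem = stem[:-1]  # stopped -> stop
        return stem
    if word.endswith("ing") and len(word) > 4:
        stem = word[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS + "sl":
            stem = stem[:-1]  # running -> run
        return stem
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        if word.endswith("es") and word[:-2].endswith(("sh", "ch", "x", "z")):
            return word[:-2]
        return word[:-1]
    return word


def normalize_trigger(mention: str) -> str:
    """Canonical trigger form: lowercase, drop trailing prepositions/articles,
    lemmatize the remaining head (last) word."""
    tokens = mention.lower().split()
    if not tokens:
        raise ValueError("empty trigger mention")
    while tokens and tokens[-1] in _PREPOSITIONS:
        tokens.pop()
    if not tokens:  # mention was all prepositions; fall back to raw form
        tokens = mention.lower().split()
    return _lemmatize(tokens[-1])


def trigger_counts(
    corpus: Iterable[StandoffDocument], rtype: str
) -> Counter[str]:
    """Normalized trigger frequencies over trigger-bearing relations of rtype."""
    counts: Counter[str] = Counter()
    for doc in corpus:
        trigs = doc.trigger_by_id()
        for r in doc.relations:
            if r.rtype == rtype and r.trigger_id is not None:
                counts[normalize_trigger(trigs[r.trigger_id].mention)] += 1
    return counts


def top_k_trigger_coverage(
    corpus: Sequence[StandoffDocument], rtype: str, k: int
) -> float:
    """Percentage of rtype's trigger-bearing relations covered by its k most
    frequent normalized triggers."""
    counts = trigger_counts(corpus, rtype)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no trigger-bearing {rtype} relations in corpus")
    top = sum(c for _, c in counts.most_common(k))
    return 100.0 * top / total


def concept_frequency(
    corpus: Iterable[StandoffDocument],
    etype: str,
    rtype: str | None = None,
    disease_filter: str | None = None,
    tree_numbers: Mapping[str, str] | None = None,
) -> ConceptRanking:
    """Rank concept ids of ``etype`` by how many relations they join.

    Mentions aggregate by concept id; each entry is named by the concept's
    most frequent surface form (lowercased).  ``rtype`` restricts to one
    relation type; ``disease_filter`` keeps only relations whose disease
    concept matches the given id, or -- when ``tree_numbers`` maps ids to
    MeSH tree numbers -- whose tree number starts with a ``filter`` ending
    in ``*`` (e.g. ``C04.*``).
    """
    counts: Counter[str] = Counter()
    names: dict[str, Counter[str]] = {}
    for doc in corpus:
        ents = doc.entity_by_id()
        for r in doc.relations:
            if rtype is not None and r.rtype != rtype:
                continue
            plant, disease = ents[r.plant_id], ents[r.disease_id]
            if disease_filter is not None and not _disease_matches(
                disease.concept_id, disease_filter, tree_numbers
            ):
                continue
            target = plant if etype == "Plant" else disease
            cid = target.concept_id or target.mention.lower()
            counts[cid] += 1
            names.setdefault(cid, Counter())[target.mention.lower()] += 1
    entries = sorted(
        ((names[cid].most_common(1)[0][0], cid, n) for cid, n in counts.items()),
        key=lambda e: (-e[2], e[0]),
    )
    return ConceptRanking(tuple(entries))


def _disease_matches(
    concept_id: str | None,
    disease_filter: str,
    tree_numbers: Mapping[str, str] | None,
) -> bool:
    if concept_id is None:
        return False
    if disease_filter.endswith("*"):
        if tree_numbers is None:
            return False
        tree = tree_numbers.get(concept_id, "")
        return tree.startswith(disease_filter[:-1])
    return concept_id == disease_filter


@dataclass(frozen=True)
class SectionStats:
    """Sentence/relation counts for one section (title or abstract)."""

    sentences: int
    relations: int
    by_type: dict[str, int]

    @property
    def relation_rate(self) -> float:
        """Relations per 100 sentences."""
        return 100.0 * self.relations / self.sentences if self.sentences else 0.0

    def type_percentage(self, rtype: str) -> float:
        if self.relations == 0:
            return 0.0
        return 100.0 * self.by_type.get(rtype, 0) / self.relations


def section_stats(
    corpus: Iterable[StandoffDocument],
    sentences_per_doc: Mapping[str, Sequence[Span]],
) -> dict[str, SectionStats]:
    """Title vs abstract statistics.

    The title is the first line of each text; a sentence belongs to the
    title section iff it ends before the first newline.  Each relation is
    assigned to the sentence containing both of its arguments.
    """
    sent_n = {"title": 0, "abstract": 0}
    rel_n = {"title": 0, "abstract": 0}
    by_type = {
        "title": {t: 0 for t in RELATION_TYPES},
        "abstract": {t: 0 for t in RELATION_TYPES},
    }
    for doc in corpus:
        sentences = sentences_per_doc[doc.doc_id]
        title_end = doc.text.find("\n")
        if title_end < 0:
            title_end = len(doc.text)
        section_of = [
            "title" if s.end <= title_end else "abstract" for s in sentences
        ]
        for sec in section_of:
            sent_n[sec] += 1
        ents = doc.entity_by_id()
        for r in doc.relations:
            plant, disease = ents[r.plant_id], ents[r.disease_id]
            for s, sec in zip(sentences, section_of):
                if s.contains(plant.span) and s.contains(disease.span):
                    rel_n[sec] += 1
                    by_type[sec][r.rtype] += 1
                    break
    return {
        sec: SectionStats(sent_n[sec], rel_n[sec], by_type[sec])
        for sec in ("title", "abstract")
    }


def relations_per_abstract(corpus: Sequence[StandoffDocument]) -> float:
    """Mean relations per document, rounded to 2 decimals for display."""
    docs = list(corpus)
    if not docs:
        raise ValueError("empty corpus")
    total = sum(len(d.relations) for d in docs)
    return round(total / len(docs), 2)
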
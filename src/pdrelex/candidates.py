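"""Candidate relation extraction: dictionary plant NER and co-occurrence.

The pipeline mirrors how corpus candidates are selected from abstracts:
plant mentions are tagged with a dictionary matcher over taxonomy names
(with a stoplist for hazardous synonyms such as "anemia" or "lens"),
disease annotations are consumed from PubTator-style offset files, text is
split into sentences, and every plant x disease pair sharing a sentence
becomes a candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .standoff import EntityAnnotation, Span

__all__ = [
    "DictionaryEntry",
    "CandidatePair",
    "PlantMatcher",
    "compile_matcher",
    "tag_plants",
    "split_sentences",
    "candidate_pairs",
    "read_dictionary",
    "read_stoplist",
    "read_pubtator",
]

# Short all-uppercase dictionary names (<= this many chars) are matched
# case-sensitively; they are usually acronyms ("NAME") that would otherwise
# fire on ordinary words.
_EXACT_CASE_MAX_LEN = 4

_TOKEN_RE = re.compile(r"\w+(?:[-']\w+)*", re.UNICODE)


@dataclass(frozen=True)
class DictionaryEntry:
    name: str
    concept_id: str

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("dictionary name must be non-empty")


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    sentence: Span
    plant: EntityAnnotation
    disease: EntityAnnotation


class PlantMatcher:
    """Case-insensitive, token-boundary, leftmost-longest dictionary matcher.

    Names are token sequences; a candidate match must start and end on token
    boundaries.  At each position the longest matching dictionary name wins
    and matching resumes after it, so matches never overlap.  Short
    all-uppercase names require an exact-case hit.
    """

    def __init__(self, entries: Iterable[DictionaryEntry], stoplist: Iterable[str] = ()):
        stop = {s.strip().lower() for s in stoplist if s.strip()}
        self._by_first: dict[str, list[tuple[tuple[str, ...], str, bool]]] = {}
        n = 0
        seen: dict[str, str] = {}
        for entry in entries:
            key = entry.name.lower()
            if key in stop:
                continue
            if key in seen:
                if seen[key] != entry.concept_id:
                    import warnings

                    warnings.warn(
                        f"homonym {entry.name!r}: keeping first id {seen[key]}",
                        stacklevel=3,
                    )
                continue
            seen[key] = entry.concept_id
            tokens = tuple(t.lower() for t in _TOKEN_RE.findall(entry.name))
            if not tokens:
                continue
            exact = entry.name.isupper() and len(entry.name) <= _EXACT_CASE_MAX_LEN
            self._by_first.setdefault(tokens[0] if not exact else entry.name, []).append(
                (tokens if not exact else (entry.name,), entry.concept_id, exact)
            )
            n += 1
        if n == 0:
            raise ValueError("dictionary is empty after applying the stoplist")
        for cands in self._by_first.values():
            cands.sort(key=lambda c: -len(c[0]))

    def find(self, text: str) -> list[tuple[Span, str]]:
        """Return (span, concept_id) for every match, leftmost-longest."""
        tokens = [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
        out: list[tuple[Span, str]] = []
        i = 0
        while i < len(tokens):
            form, start, _ = tokens[i]
            candidates = self._by_first.get(form.lower(), []) + self._by_first.get(form, [])
            best: tuple[int, Span, str] | None = None
            for name_tokens, cid, exact in candidates:
                L = len(name_tokens)
                if i + L > len(tokens):
                    continue
                window = tokens[i : i + L]
                if exact:
                    ok = L == 1 and window[0][0] == name_tokens[0]
                else:
                    ok = all(w[0].lower() == nt for w, nt in zip(window, name_tokens))
                if ok and (best is None or L > best[0]):
                    best = (L, Span(window[0][1], window[-1][2]), cid)
            if best is not None:
                out.append((best[1], best[2]))
                i += best[0]
            else:
                i += 1
        return out


def compile_matcher(
    entries: Sequence[DictionaryEntry], stoplist: Iterable[str] = ()
) -> PlantMatcher:
    if not entries:
        raise ValueError("dictionary must be non-empty")
    return PlantMatcher(entries, stoplist)


def tag_plants(text: str, matcher: PlantMatcher) -> list[EntityAnnotation]:
    """Tag Plant mentions; ids are assigned T1.. in offset order."""
    return [
        EntityAnnotation(f"T{i}", "Plant", span, text[span.start : span.end], cid)
        for i, (span, cid) in enumerate(matcher.find(text), start=1)
    ]


_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+|\n+")


def split_sentences(text: str) -> list[Span]:
    """Split into sentence spans; never merges across the title newline.

    Boundaries fall after sentence-final punctuation and at newlines, so a
    two-sentence title line yields two spans.  Spans are trimmed of
    surrounding whitespace and cover all non-whitespace text in order.
    """
    spans: list[Span] = []
    pos = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        _push_trimmed(spans, text, pos, m.start())
        pos = m.end()
    _push_trimmed(spans, text, pos, len(text))
    return spans


def _push_trimmed(spans: list[Span], text: str, start: int, end: int) -> None:
    chunk = text[start:end]
    left = len(chunk) - len(chunk.lstrip())
    right = len(chunk.rstrip())
    if right > left:
        spans.append(Span(start + left, start + right))


def candidate_pairs(
    doc_id: str,
    sentence: Span,
    plants: Sequence[EntityAnnotation],
    diseases: Sequence[EntityAnnotation],
) -> list[CandidatePair]:
    """Cartesian product of in-sentence plants x diseases.

    Ordered by plant offset then disease offset; entities outside the
    sentence raise ValueError.
    """
    for e in [*plants, *diseases]:
        if not sentence.contains(e.span):
            raise ValueError(f"entity {e.id} not inside sentence {sentence}")
    return [
        CandidatePair(doc_id, sentence, p, d)
        for p in sorted(plants, key=lambda e: e.span)
        for d in sorted(diseases, key=lambda e: e.span)
    ]


# ---------------------------------------------------------------------------
# readers

def read_dictionary(source: str | Path | Iterable[str]) -> list[DictionaryEntry]:
    """Read ``name<TAB>taxonomy_id`` lines."""
    out = []
    for line in _lines(source):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"bad dictionary line: {line!r}")
        out.append(DictionaryEntry(parts[0], parts[1]))
    return out


def read_stoplist(source: str | Path | Iterable[str]) -> set[str]:
    return {line for line in _lines(source)}


def read_pubtator(source: str | Path | Iterable[str]) -> dict[str, list[EntityAnnotation]]:
    """Read ``PMID<TAB>start<TAB>end<TAB>mention<TAB>type<TAB>id`` offsets.

    Returns annotations grouped by PMID with ids assigned per document.
    """
    grouped: dict[str, list[EntityAnnotation]] = {}
    for line in _lines(source):
        parts = line.split("\t")
        if len(parts) < 5:
            raise ValueError(f"bad PubTator line: {line!r}")
        pmid, start, end, mention, etype = parts[:5]
        concept = parts[5] if len(parts) > 5 and parts[5] else None
        annots = grouped.setdefault(pmid, [])
        annots.append(
            EntityAnnotation(
                f"T{len(annots) + 1}",
                etype.capitalize(),
                Span(int(start), int(end)),
                mention,
                concept,
            )
        )
    return grouped


def _lines(source: str | Path | Iterable[str]) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        content = Path(source).read_text()
        lines: Iterable[str] = content.splitlines()
    else:
        lines = source
    for line in lines:
        line = line.rstrip("\n")
        if line.strip():
            yield line
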
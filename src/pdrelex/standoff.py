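"""Standoff (txt/a1/a2) corpus I/O and structural validation.

One abstract is stored as three files in the BioNLP shared-task style:

* ``<PMID>.txt``  -- plain text; the first line is the title.
* ``<PMID>.a1``   -- entity lines ``T1<TAB>Plant 0 6<TAB>Coffee`` followed by
  normalization lines ``N1<TAB>Reference T1<TAB>Taxonomy:13443`` carrying the
  concept identifier (NCBI Taxonomy id for plants, MEDIC id for diseases).
  A lenient reader also accepts the concept id as a trailing tab column on
  the entity line itself.
* ``<PMID>.a2``   -- trigger lines (same shape as entity lines, typed by
  relation type), event lines ``E1<TAB>ToD:T9 Cause:T1 Theme:T2`` for
  relations with a trigger, relation lines ``R1<TAB>CoD Arg1:T1 Arg2:T2``
  for trigger-less relations, and equivalence lines ``*<TAB>Equiv T1 T5``.

Character offsets are 0-based and end-exclusive over the raw text including
the newline after the title.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Span",
    "EntityAnnotation",
    "TriggerAnnotation",
    "RelationAnnotation",
    "EquivAnnotation",
    "StandoffDocument",
    "Violation",
    "StandoffParseError",
    "StandoffValidationError",
    "FlatRelationRecord",
    "FlatTableError",
    "parse_document",
    "write_document",
    "validate_document",
    "parse_flat_table",
    "flat_records",
    "read_corpus",
    "write_corpus",
]

RELATION_TYPES = ("ToD", "CoD", "Association", "Negative")
POSITIVE_TYPES = ("ToD", "CoD", "Association")
ENTITY_TYPES = ("Plant", "Disease")

_MEDIC_RE = re.compile(r"^(?:[DC]\d{6}|OMIM:\d+)$")
_TAXID_RE = re.compile(r"^\d+$")


class StandoffParseError(ValueError):
    """A malformed standoff line; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class StandoffValidationError(ValueError):
    """Raised when a document violates the structural invariants."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__(
            "; ".join(str(v) for v in self.violations) or "invalid document"
        )


@dataclass(frozen=True, order=True)
class Span:
    """Character span, 0-based start (inclusive) to end (exclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class EntityAnnotation:
    id: str
    etype: str  # "Plant" | "Disease"
    span: Span
    mention: str
    concept_id: str | None = None


@dataclass(frozen=True)
class TriggerAnnotation:
    id: str
    rtype: str  # "ToD" | "CoD" | "Association"
    span: Span
    mention: str


@dataclass(frozen=True)
class RelationAnnotation:
    id: str
    rtype: str  # one of RELATION_TYPES
    plant_id: str  # Arg1 / Cause
    disease_id: str  # Arg2 / Theme
    trigger_id: str | None = None


@dataclass(frozen=True)
class EquivAnnotation:
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("Equiv needs at least two members")


@dataclass
class StandoffDocument:
    """One abstract with its standoff annotations (title = first text line)."""

    doc_id: str
    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    triggers: list[TriggerAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    equivs: list[EquivAnnotation] = field(default_factory=list)

    @property
    def title(self) -> str:
        return self.text.split("\n", 1)[0]

    def entity_by_id(self) -> dict[str, EntityAnnotation]:
        return {e.id: e for e in self.entities}

    def trigger_by_id(self) -> dict[str, TriggerAnnotation]:
        return {t.id: t for t in self.triggers}

    def sorted(self) -> "StandoffDocument":
        """Canonical ordering: entities/triggers by offset, relations by id."""
        return StandoffDocument(
            doc_id=self.doc_id,
            text=self.text,
            entities=sorted(self.entities, key=lambda e: (e.span, _id_key(e.id))),
            triggers=sorted(self.triggers, key=lambda t: (t.span, _id_key(t.id))),
            relations=sorted(self.relations, key=lambda r: _id_key(r.id)),
            equivs=sorted(self.equivs, key=lambda q: sorted(_id_key(m) for m in q.member_ids)),
        )


@dataclass(frozen=True)
class Violation:
    """A structural problem found by :func:`validate_document`."""

    code: str
    ids: tuple[str, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {' '.join(self.ids)}: {self.message}"


def _id_key(annot_id: str) -> tuple[str, int]:
    m = re.match(r"^([A-Za-z*]*)(\d*)$", annot_id)
    if not m:
        return (annot_id, 0)
    prefix, num = m.groups()
    return (prefix, int(num) if num else 0)


# ---------------------------------------------------------------------------
# parsing

_ANNOT_LINE_RE = re.compile(r"^(\S+)\t([^\t]+)(?:\t(.*))?$")


def _parse_typed_span_line(
    annot_id: str, mid: str, rest: str | None, line_no: int
) -> tuple[str, Span, str, str | None]:
    """Parse ``<Type> <start> <end>`` + mention (+ optional bare concept id)."""
    parts = mid.split(" ")
    if len(parts) != 3:
        raise StandoffParseError(
            f"expected '<Type> <start> <end>' in {annot_id!r}, got {mid!r}", line_no
        )
    typ, s, e = parts
    try:
        span = Span(int(s), int(e))
    except ValueError as exc:
        raise StandoffParseError(f"bad span in {annot_id!r}: {exc}", line_no) from exc
    mention = rest or ""
    concept = None
    if "\t" in mention:  # lenient: trailing tab-separated concept id column
        mention, concept = mention.split("\t", 1)
        concept = concept.strip() or None
    return typ, span, mention, concept


_ARG_RE = re.compile(r"^(\w+):(\S+)$")


def parse_document(
    txt_content: str, a1_content: str, a2_content: str, doc_id: str = ""
) -> StandoffDocument:
    """Parse one abstract from its txt/a1/a2 contents.

    Unknown line types raise :class:`StandoffParseError` (they are reported,
    never silently dropped).  Mentions that disagree with the text at their
    span raise :class:`StandoffValidationError` naming the offending id.
    """
    doc = StandoffDocument(doc_id=doc_id, text=txt_content)
    concept_refs: dict[str, str] = {}

    for line_no, raw in _numbered_lines(a1_content):
        m = _ANNOT_LINE_RE.match(raw)
        if not m:
            raise StandoffParseError(f"malformed a1 line: {raw!r}", line_no)
        annot_id, mid, rest = m.group(1), m.group(2), raw.split("\t", 2)[2] if raw.count("\t") >= 2 else None
        if annot_id.startswith("T"):
            etype, span, mention, concept = _parse_typed_span_line(annot_id, mid, rest, line_no)
            if etype not in ENTITY_TYPES:
                raise StandoffParseError(f"unknown entity type {etype!r}", line_no)
            doc.entities.append(EntityAnnotation(annot_id, etype, span, mention, concept))
        elif annot_id.startswith("N"):
            parts = mid.split(" ")
            if len(parts) != 2 or parts[0] != "Reference":
                raise StandoffParseError(f"malformed normalization line: {raw!r}", line_no)
            target = parts[1]
            ref = (rest or "").strip()
            concept_refs[target] = ref.split(":", 1)[1] if ":" in ref else ref
        else:
            raise StandoffParseError(f"unknown a1 line type {annot_id!r}", line_no)

    if concept_refs:
        doc.entities = [
            replace(e, concept_id=concept_refs.get(e.id, e.concept_id))
            for e in doc.entities
        ]

    for line_no, raw in _numbered_lines(a2_content):
        m = _ANNOT_LINE_RE.match(raw)
        if not m:
            raise StandoffParseError(f"malformed a2 line: {raw!r}", line_no)
        annot_id, mid = m.group(1), m.group(2)
        rest = raw.split("\t", 2)[2] if raw.count("\t") >= 2 else None
        if annot_id.startswith("T"):
            rtype, span, mention, _ = _parse_typed_span_line(annot_id, mid, rest, line_no)
            if rtype not in POSITIVE_TYPES:
                raise StandoffParseError(f"unknown trigger type {rtype!r}", line_no)
            doc.triggers.append(TriggerAnnotation(annot_id, rtype, span, mention))
        elif annot_id.startswith("E"):
            doc.relations.append(_parse_event_line(annot_id, mid, line_no))
        elif annot_id.startswith("R"):
            doc.relations.append(_parse_relation_line(annot_id, mid, line_no))
        elif annot_id == "*":
            parts = mid.split(" ")
            if len(parts) < 3 or parts[0] != "Equiv":
                raise StandoffParseError(f"malformed Equiv line: {raw!r}", line_no)
            doc.equivs.append(EquivAnnotation(frozenset(parts[1:])))
        else:
            raise StandoffParseError(f"unknown a2 line type {annot_id!r}", line_no)

    mismatches = [
        v for v in validate_document(doc) if v.code in ("mention-mismatch", "span-bounds")
    ]
    if mismatches:
        raise StandoffValidationError(mismatches)
    return doc


def _numbered_lines(content: str) -> Iterable[tuple[int, str]]:
    for i, line in enumerate(content.splitlines(), start=1):
        if line.strip():
            yield i, line


def _parse_event_line(annot_id: str, mid: str, line_no: int) -> RelationAnnotation:
    parts = mid.split(" ")
    head = parts[0]
    if ":" not in head:
        raise StandoffParseError(f"event head must be Type:Trigger, got {head!r}", line_no)
    rtype, trigger_id = head.split(":", 1)
    args = _parse_args(parts[1:], line_no)
    if "Cause" not in args or "Theme" not in args:
        raise StandoffParseError("event needs Cause and Theme arguments", line_no)
    return RelationAnnotation(annot_id, rtype, args["Cause"], args["Theme"], trigger_id)


def _parse_relation_line(annot_id: str, mid: str, line_no: int) -> RelationAnnotation:
    parts = mid.split(" ")
    rtype = parts[0]
    args = _parse_args(parts[1:], line_no)
    if "Arg1" not in args or "Arg2" not in args:
        raise StandoffParseError("relation needs Arg1 and Arg2", line_no)
    return RelationAnnotation(annot_id, rtype, args["Arg1"], args["Arg2"], None)


def _parse_args(tokens: Sequence[str], line_no: int) -> dict[str, str]:
    args: dict[str, str] = {}
    for tok in tokens:
        m = _ARG_RE.match(tok)
        if not m:
            raise StandoffParseError(f"malformed argument {tok!r}", line_no)
        args[m.group(1)] = m.group(2)
    return args


# ---------------------------------------------------------------------------
# writing

def write_document(doc: StandoffDocument) -> tuple[str, str, str]:
    """Serialize to (txt, a1, a2) contents; refuses invalid documents.

    Output is deterministic: entities and triggers ordered by offset,
    relations by id, normalization lines numbered in entity order.
    """
    hard = [
        v
        for v in validate_document(doc)
        if v.code in ("span-bounds", "mention-mismatch", "duplicate-id", "dangling-ref")
    ]
    if hard:
        raise StandoffValidationError(hard)

    canon = doc.sorted()
    a1_lines: list[str] = []
    norm_lines: list[str] = []
    n = 0
    for e in canon.entities:
        a1_lines.append(f"{e.id}\t{e.etype} {e.span.start} {e.span.end}\t{e.mention}")
        if e.concept_id is not None:
            n += 1
            ns = "Taxonomy" if e.etype == "Plant" else "MEDIC"
            norm_lines.append(f"N{n}\tReference {e.id}\t{ns}:{e.concept_id}")

    a2_lines: list[str] = []
    for t in canon.triggers:
        a2_lines.append(f"{t.id}\t{t.rtype} {t.span.start} {t.span.end}\t{t.mention}")
    for r in canon.relations:
        if r.trigger_id is not None:
            a2_lines.append(
                f"{r.id}\t{r.rtype}:{r.trigger_id} Cause:{r.plant_id} Theme:{r.disease_id}"
            )
        else:
            a2_lines.append(f"{r.id}\t{r.rtype} Arg1:{r.plant_id} Arg2:{r.disease_id}")
    for q in canon.equivs:
        members = " ".join(sorted(q.member_ids, key=_id_key))
        a2_lines.append(f"*\tEquiv {members}")

    def _join(lines: list[str]) -> str:
        return "\n".join(lines) + ("\n" if lines else "")

    return doc.text, _join(a1_lines + norm_lines), _join(a2_lines)


# ---------------------------------------------------------------------------
# validation

def validate_document(
    doc: StandoffDocument, sentences: Sequence[Span] | None = None
) -> list[Violation]:
    """Return structural violations; an empty list means compliant.

    Violations are data, not exceptions.  When ``sentences`` is supplied the
    same-sentence constraint on relation arguments is checked as well.
    """
    out: list[Violation] = []
    text_len = len(doc.text)

    seen: set[str] = set()
    for a in [*doc.entities, *doc.triggers, *doc.relations]:
        if a.id in seen:
            out.append(Violation("duplicate-id", (a.id,), "annotation id reused"))
        seen.add(a.id)

    for e in doc.entities:
        out.extend(_check_span(doc, e.id, e.span, e.mention, text_len))
        if e.concept_id is not None:
            ok = (
                _TAXID_RE.match(e.concept_id)
                if e.etype == "Plant"
                else _MEDIC_RE.match(e.concept_id)
            )
            if not ok:
                out.append(
                    Violation(
                        "concept-id-format",
                        (e.id,),
                        f"{e.etype} concept id {e.concept_id!r} has unexpected form",
                    )
                )
    for t in doc.triggers:
        out.extend(_check_span(doc, t.id, t.span, t.mention, text_len))
        if t.rtype not in POSITIVE_TYPES:
            out.append(Violation("trigger-type", (t.id,), f"bad trigger type {t.rtype!r}"))

    ents = doc.entity_by_id()
    trigs = doc.trigger_by_id()
    for r in doc.relations:
        if r.rtype not in RELATION_TYPES:
            out.append(Violation("relation-type", (r.id,), f"unknown type {r.rtype!r}"))
        plant = ents.get(r.plant_id)
        disease = ents.get(r.disease_id)
        if plant is None or disease is None:
            out.append(Violation("dangling-ref", (r.id,), "argument id not found"))
            continue
        if plant.etype != "Plant":
            out.append(
                Violation("arg-type", (r.id, r.plant_id), "Arg1/Cause must be a Plant")
            )
        if disease.etype != "Disease":
            out.append(
                Violation("arg-type", (r.id, r.disease_id), "Arg2/Theme must be a Disease")
            )
        if r.rtype == "Negative" and r.trigger_id is not None:
            out.append(
                Violation("negative-with-trigger", (r.id,), "Negative relations have no trigger")
            )
        if r.trigger_id is not None:
            trig = trigs.get(r.trigger_id)
            if trig is None:
                out.append(Violation("dangling-ref", (r.id, r.trigger_id), "trigger not found"))
            elif trig.rtype != r.rtype:
                out.append(
                    Violation(
                        "trigger-type-mismatch",
                        (r.id, r.trigger_id),
                        f"trigger typed {trig.rtype}, relation typed {r.rtype}",
                    )
                )
        if sentences is not None and plant is not None and disease is not None:
            if not any(
                s.contains(plant.span) and s.contains(disease.span) for s in sentences
            ):
                out.append(
                    Violation(
                        "cross-sentence",
                        (r.id,),
                        "plant and disease do not share a sentence",
                    )
                )

    for q in doc.equivs:
        types = {ents[m].etype for m in q.member_ids if m in ents}
        if any(m not in ents for m in q.member_ids):
            out.append(Violation("dangling-ref", tuple(sorted(q.member_ids)), "Equiv member missing"))
        elif len(types) > 1:
            out.append(
                Violation("equiv-mixed-type", tuple(sorted(q.member_ids)), "Equiv mixes entity types")
            )
    return out


def _check_span(
    doc: StandoffDocument, annot_id: str, span: Span, mention: str, text_len: int
) -> list[Violation]:
    if span.end > text_len:
        return [Violation("span-bounds", (annot_id,), f"span {span} beyond text end {text_len}")]
    actual = doc.text[span.start : span.end]
    if actual != mention:
        return [
            Violation(
                "mention-mismatch",
                (annot_id,),
                f"mention {mention!r} != text {actual!r} at {span}",
            )
        ]
    return []


# ---------------------------------------------------------------------------
# flat relation table (one row per relation)

FLAT_COLUMNS = (
    "pmid",
    "sentence_id",
    "relation_id",
    "sentence",
    "plant_mention",
    "plant_id",
    "disease_mention",
    "disease_id",
    "category",
    "trigger",
)

_COLUMN_SYNONYMS: Mapping[str, str] = {
    "pmid": "pmid",
    "pubmed id": "pmid",
    "sentence id": "sentence_id",
    "sentence_id": "sentence_id",
    "relation id": "relation_id",
    "relation_id": "relation_id",
    "sentence": "sentence",
    "sentence with entity indicator": "sentence",
    "plant": "plant_mention",
    "plant mention": "plant_mention",
    "plant_mention": "plant_mention",
    "plant id": "plant_id",
    "plant_id": "plant_id",
    "disease": "disease_mention",
    "disease mention": "disease_mention",
    "disease indication": "disease_mention",
    "disease_mention": "disease_mention",
    "disease id": "disease_id",
    "disease_id": "disease_id",
    "category": "category",
    "relation category": "category",
    "relation type": "category",
    "trigger": "trigger",
    "trigger mention": "trigger",
}

_CATEGORY_MAP = {
    "tod": "ToD",
    "treatment of disease": "ToD",
    "cod": "CoD",
    "cause of disease": "CoD",
    "association": "Association",
    "assoc": "Association",
    "negative": "Negative",
    "neg": "Negative",
}


class FlatTableError(ValueError):
    pass


@dataclass(frozen=True)
class FlatRelationRecord:
    pmid: str
    sentence_id: str
    relation_id: str
    sentence: str
    plant_mention: str
    plant_id: str | None
    disease_mention: str
    disease_id: str | None
    category: str  # one of RELATION_TYPES
    trigger: str | None


def parse_flat_table(
    rows: "pd.DataFrame | str | Path | Iterable[Mapping[str, object]]",
    column_synonyms: Mapping[str, str] | None = None,
) -> list[FlatRelationRecord]:
    """Parse a flat relation table (CSV/XLSX path, DataFrame, or dict rows).

    Relation categories are mapped onto {ToD, CoD, Association, Negative};
    an unknown label raises :class:`FlatTableError` naming the row.
    """
    if isinstance(rows, (str, Path)):
        path = Path(rows)
        frame = (
            pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(path)
        )
    elif isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        frame = pd.DataFrame(list(rows))

    synonyms = dict(_COLUMN_SYNONYMS)
    if column_synonyms:
        synonyms.update({k.strip().lower(): v for k, v in column_synonyms.items()})

    rename = {}
    for col in frame.columns:
        key = str(col).strip().lower()
        if key in synonyms:
            rename[col] = synonyms[key]
    frame = frame.rename(columns=rename)

    missing = {"pmid", "category", "plant_mention", "disease_mention"} - set(frame.columns)
    if missing:
        raise FlatTableError(f"missing required columns: {sorted(missing)}")

    records: list[FlatRelationRecord] = []
    for idx, row in frame.iterrows():
        raw_cat = str(row["category"]).strip()
        cat = _CATEGORY_MAP.get(raw_cat.lower())
        if cat is None:
            raise FlatTableError(f"row {idx}: unknown relation category {raw_cat!r}")
        records.append(
            FlatRelationRecord(
                pmid=str(row["pmid"]),
                sentence_id=_opt_str(row.get("sentence_id")) or "",
                relation_id=_opt_str(row.get("relation_id")) or "",
                sentence=_opt_str(row.get("sentence")) or "",
                plant_mention=str(row["plant_mention"]),
                plant_id=_opt_str(row.get("plant_id")),
                disease_mention=str(row["disease_mention"]),
                disease_id=_opt_str(row.get("disease_id")),
                category=cat,
                trigger=_opt_str(row.get("trigger")),
            )
        )
    return records


def _opt_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def flat_records(
    doc: StandoffDocument, sentences: Sequence[Span]
) -> list[FlatRelationRecord]:
    """Flatten a document's relations into S1-style rows.

    ``sentences`` is a precomputed segmentation of ``doc.text``; the sentence
    column carries ``e1start``/``e1end``/``e2start``/``e2end`` indicators
    around the two argument mentions.
    """
    ents = doc.entity_by_id()
    trigs = doc.trigger_by_id()
    out: list[FlatRelationRecord] = []
    for r in sorted(doc.relations, key=lambda r: _id_key(r.id)):
        plant, disease = ents[r.plant_id], ents[r.disease_id]
        sent_idx, sent_span = _containing_sentence(sentences, plant.span, disease.span)
        sent_text = doc.text[sent_span.start : sent_span.end] if sent_span else ""
        if sent_span:
            sent_text = _with_indicators(doc.text, sent_span, plant.span, disease.span)
        out.append(
            FlatRelationRecord(
                pmid=doc.doc_id,
                sentence_id=str(sent_idx),
                relation_id=r.id,
                sentence=sent_text,
                plant_mention=plant.mention,
                plant_id=plant.concept_id,
                disease_mention=disease.mention,
                disease_id=disease.concept_id,
                category=r.rtype,
                trigger=trigs[r.trigger_id].mention if r.trigger_id else None,
            )
        )
    return out


def _containing_sentence(
    sentences: Sequence[Span], a: Span, b: Span
) -> tuple[int, Span | None]:
    for i, s in enumerate(sentences):
        if s.contains(a) and s.contains(b):
            return i, s
    return -1, None


def _with_indicators(text: str, sent: Span, plant: Span, disease: Span) -> str:
    inserts = sorted(
        [
            (plant.start, " e1start "),
            (plant.end, " e1end "),
            (disease.start, " e2start "),
            (disease.end, " e2end "),
        ],
        reverse=True,
    )
    s = text[sent.start : sent.end]
    for pos, tag in inserts:
        rel = pos - sent.start
        s = s[:rel] + tag + s[rel:]
    return " ".join(s.split())


# ---------------------------------------------------------------------------
# corpus directories

def read_corpus(directory: str | Path) -> list[StandoffDocument]:
    """Read every ``<PMID>.txt``/``.a1``/``.a2`` triple under ``directory``."""
    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        doc_id = txt_path.stem
        a1 = txt_path.with_suffix(".a1")
        a2 = txt_path.with_suffix(".a2")
        docs.append(
            parse_document(
                txt_path.read_text(),
                a1.read_text() if a1.exists() else "",
                a2.read_text() if a2.exists() else "",
                doc_id=doc_id,
            )
        )
    return docs


def write_corpus(docs: Iterable[StandoffDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        txt, a1, a2 = write_document(doc)
        (directory / f"{doc.doc_id}.txt").write_text(txt)
        (directory / f"{doc.doc_id}.a1").write_text(a1)
        (directory / f"{doc.doc_id}.a2").write_text(a2)
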
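"""Corpus-level synthesis: slot allocation, document assembly, manifest.

The generator's defaults reproduce the composition of the annotated
plant-disease corpus: 1,309 relations over 199 abstracts split 508/183/34
into treatment-of-disease (ToD), cause-of-disease (CoD) and Association
positives plus 584 negatives; per-type trigger-bearing fractions 432/508,
157/183, 32/34; the title/abstract split of relations (145 in titles over
202 title sentences, the rest over 1,950 abstract sentences); per-type
trigger frequency tables (e.g. effect/reduce/prevent/protect/decrease as
the top ToD triggers); and per-type plant concept tables (e.g. tobacco,
taxonomy id 4097, joining 116 of the 183 CoD relations).  Other corpus
sizes scale every table by largest-remainder allocation, or -- with
``exact_composition=False`` -- sample relation types multinomially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ..sdp import DependencyGraph
from ..standoff import (
    EntityAnnotation,
    EquivAnnotation,
    RelationAnnotation,
    Span,
    StandoffDocument,
    TriggerAnnotation,
)
from .templates import (
    EXTRA_TITLE_SENTENCE,
    FILLER_SENTENCES,
    GENERIC_TITLES,
    NEGATIVE_TEMPLATES,
    TEMPLATES,
    TRANSITIVE_TOD_TRIGGERS,
    TRIGGER_REALIZATIONS,
    TRIGGERLESS_TEMPLATES,
    RealizedSentence,
    realize,
)

__all__ = [
    "GeneratorConfig",
    "Manifest",
    "TemplateParserAdapter",
    "generate_corpus",
    "generate_sentence",
]

# Reference composition of the annotated corpus (199 abstracts).
BASE_ABSTRACTS = 199
BASE_TYPE_TOTALS = {"ToD": 508, "CoD": 183, "Association": 34, "Negative": 584}
BASE_WITH_TRIGGER = {"ToD": 432, "CoD": 157, "Association": 32, "Negative": 0}
BASE_TITLE_RELATIONS = {"ToD": 69, "CoD": 14, "Association": 1, "Negative": 61}
BASE_TITLE_SENTENCES = 202
BASE_ABSTRACT_SENTENCES = 1950

BASE_TRIGGER_TABLES: dict[str, dict[str, int]] = {
    # top-5 rows follow the corpus tables; the tail triggers fill the per-type
    # trigger-bearing totals with counts strictly below the 5th rank so the
    # top-5 set is stable
    "ToD": {
        "effect": 71, "reduce": 69, "prevent": 62, "protect": 36, "decrease": 35,
        "improve": 34, "treat": 33, "inhibit": 32, "attenuate": 31, "ameliorate": 29,
    },
    "CoD": {
        "relate": 57, "associate": 23, "induce": 20, "increase": 13, "risk": 9,
        "cause": 8, "promote": 8, "exacerbate": 8, "provoke": 8, "aggravate": 3,
    },
    "Association": {"associate": 26, "effect": 4, "relate": 1, "influence": 1},
    "Negative": {},
}

PLANTS: dict[str, str] = {
    "tobacco": "4097", "coffee": "13443", "tea": "4442", "garlic": "4682",
    "ginger": "94328", "soybean": "3847", "areca": "184734", "wheat": "4565",
    "digitalis": "4163", "cannabis": "3483", "apple": "3750", "pear": "3767",
    "ginseng": "4054", "cotton": "3635", "turmeric": "136217", "birch": "3504",
    "rice": "4530", "peanut": "3818", "ginkgo": "3310", "peppermint": "34256",
}

BASE_PLANT_TABLES: dict[str, dict[str, int]] = {
    "ToD": {
        "tea": 61, "garlic": 58, "coffee": 57, "ginger": 22, "soybean": 19,
        "turmeric": 60, "ginseng": 60, "peppermint": 60, "ginkgo": 56, "rice": 55,
    },
    "CoD": {
        "tobacco": 116, "areca": 14, "wheat": 9, "digitalis": 8, "coffee": 5,
        "cotton": 16, "cannabis": 15,
    },
    "Association": {
        "tobacco": 13, "coffee": 10, "cannabis": 4, "apple": 1, "pear": 1,
        "tea": 3, "peanut": 2,
    },
    "Negative": {
        "tobacco": 151, "coffee": 93, "tea": 61, "garlic": 46, "ginseng": 21,
        "wheat": 55, "rice": 50, "soybean": 40, "peanut": 35, "ginkgo": 32,
    },
}

DISEASES: dict[str, str] = {
    "diabetes": "D003920", "asthma": "D001249", "cancer": "D009369",
    "inflammation": "D007249", "headache": "D006261", "hypertension": "D006973",
    "obesity": "D009765", "gallbladder disease": "D005705",
    "breast cancer": "D001943", "cardiovascular disease": "D002318",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus synthesis; defaults mirror the annotated
    corpus composition (see module docstring)."""

    n_abstracts: int = BASE_ABSTRACTS
    mixture: Mapping[str, float] | None = None  # relation-type proportions
    trigger_fraction: Mapping[str, float] | None = None  # per positive type
    plant_tables: Mapping[str, Mapping[str, int]] | None = None
    disease_inventory: Mapping[str, str] | None = None
    trigger_tables: Mapping[str, Mapping[str, int]] | None = None
    multi_pair_rate: float = 0.10
    equiv_rate: float = 0.05
    exact_composition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_abstracts < 1:
            raise ValueError("need at least one abstract")
        if not (0 <= self.multi_pair_rate <= 1 and 0 <= self.equiv_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.mixture is not None:
            total = sum(self.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture must sum to 1, got {total}")


@dataclass
class Manifest:
    """Ground truth for a generated corpus, consistent by construction."""

    n_abstracts: int
    type_counts: dict[str, dict[str, int]]  # rtype -> {with, without}
    title_relations: dict[str, int]
    abstract_relations: dict[str, int]
    title_sentences: int
    abstract_sentences: int
    trigger_counts: dict[str, dict[str, int]]  # rtype -> canonical -> count
    plant_counts: dict[str, dict[str, int]]  # rtype -> concept id -> count
    negative_categories: dict[int, int]
    multi_pair_sentences: int
    equiv_pairs: int
    plant_mentions: int  # Plant entities incl. abbreviations
    dictionary_mentions: int  # Plant entities whose mention is a dictionary name
    sentences_per_doc: dict[str, list[Span]]
    gold_labels: list[tuple[str, str, str]]  # (doc id, relation id, label)
    parses: dict[str, DependencyGraph]  # sentence text -> graph

    @property
    def total_relations(self) -> int:
        return sum(c["with"] + c["without"] for c in self.type_counts.values())

    def to_json(self) -> str:
        payload = {
            "n_abstracts": self.n_abstracts,
            "type_counts": self.type_counts,
            "title_relations": self.title_relations,
            "abstract_relations": self.abstract_relations,
            "title_sentences": self.title_sentences,
            "abstract_sentences": self.abstract_sentences,
            "trigger_counts": self.trigger_counts,
            "plant_counts": self.plant_counts,
            "negative_categories": self.negative_categories,
            "multi_pair_sentences": self.multi_pair_sentences,
            "equiv_pairs": self.equiv_pairs,
            "plant_mentions": self.plant_mentions,
            "dictionary_mentions": self.dictionary_mentions,
            "sentences_per_doc": {
                k: [[s.start, s.end] for s in v]
                for k, v in self.sentences_per_doc.items()
            },
            "gold_labels": self.gold_labels,
            "parses": {k: g.to_conllu() for k, g in self.parses.items()},
        }
        return json.dumps(payload, indent=1)


class TemplateParserAdapter:
    """Parser adapter backed by the generator's template parses."""

    def __init__(self, parses: Mapping[str, DependencyGraph]):
        self._parses = dict(parses)

    def __call__(self, sentence_text: str) -> DependencyGraph:
        graph = self._parses.get(sentence_text)
        if graph is None:
            raise ValueError(f"no template parse for sentence {sentence_text!r}")
        return graph

    @classmethod
    def from_json(cls, path) -> "TemplateParserAdapter":
        payload = json.loads(open(path).read())
        return cls(
            {
                text: DependencyGraph.from_conllu(conllu).align_to_text(text)
                for text, conllu in payload["parses"].items()
            }
        )


# ---------------------------------------------------------------------------
# allocation helpers

def _largest_remainder(table: Mapping[str, int], total: int) -> dict[str, int]:
    """Scale integer counts to a new total, preserving proportions."""
    base_total = sum(table.values())
    if base_total == 0 or total == 0:
        return {k: 0 for k in table}
    quotas = {k: v * total / base_total for k, v in table.items()}
    out = {k: int(q) for k, q in quotas.items()}
    short = total - sum(out.values())
    for k in sorted(table, key=lambda k: quotas[k] - int(quotas[k]), reverse=True)[:short]:
        out[k] += 1
    return out


@dataclass
class _Slot:
    rtype: str
    has_trigger: bool
    trigger: str | None
    plant: tuple[str, str]  # (name, concept id)
    disease: tuple[str, str]
    section: str = "abstract"  # "title" | "abstract"


def _build_slots(config: GeneratorConfig, rng: np.random.Generator) -> list[_Slot]:
    factor = config.n_abstracts / BASE_ABSTRACTS
    plant_tables = config.plant_tables or BASE_PLANT_TABLES
    trigger_tables = config.trigger_tables or BASE_TRIGGER_TABLES
    diseases = list((config.disease_inventory or DISEASES).items())

    if config.exact_composition:
        grand = round(sum(BASE_TYPE_TOTALS.values()) * factor)
        if config.mixture is not None:
            type_counts = _largest_remainder(
                {k: round(v * 1000) for k, v in config.mixture.items()}, grand
            )
        else:
            type_counts = _largest_remainder(BASE_TYPE_TOTALS, grand)
    else:
        grand = round(sum(BASE_TYPE_TOTALS.values()) * factor)
        mixture = config.mixture or {
            k: v / sum(BASE_TYPE_TOTALS.values()) for k, v in BASE_TYPE_TOTALS.items()
        }
        labels = list(mixture)
        draws = rng.multinomial(grand, [mixture[k] for k in labels])
        type_counts = dict(zip(labels, (int(d) for d in draws)))

    slots: list[_Slot] = []
    for rtype, count in type_counts.items():
        if count == 0:
            continue
        if config.trigger_fraction is not None and rtype in config.trigger_fraction:
            n_trig = round(count * config.trigger_fraction[rtype])
        elif BASE_TYPE_TOTALS.get(rtype):
            n_trig = round(count * BASE_WITH_TRIGGER[rtype] / BASE_TYPE_TOTALS[rtype])
        else:
            n_trig = 0
        n_trig = min(n_trig, count)

        trig_list: list[str | None] = []
        table = trigger_tables.get(rtype, {})
        if n_trig and table:
            alloc = _largest_remainder(table, n_trig)
            for name, c in alloc.items():
                trig_list.extend([name] * c)
        trig_list.extend([None] * (count - len(trig_list)))

        plant_alloc = _largest_remainder(plant_tables.get(rtype, {"tobacco": 1}), count)
        plant_list = [
            (name, PLANTS.get(name, plant_tables.get(rtype, {}).get(name, "0")))
            for name, c in plant_alloc.items()
            for _ in range(c)
        ]
        rng.shuffle(plant_list)

        for i in range(count):
            d_name, d_id = diseases[rng.integers(len(diseases))]
            slots.append(
                _Slot(
                    rtype=rtype,
                    has_trigger=trig_list[i] is not None,
                    trigger=trig_list[i],
                    plant=plant_list[i],
                    disease=(d_name, d_id),
                )
            )

    # title assignment: scale the per-type title counts, never more than one
    # title relation per abstract
    title_counts = {
        t: min(round(BASE_TITLE_RELATIONS.get(t, 0) * factor), type_counts.get(t, 0))
        for t in type_counts
    }
    while sum(title_counts.values()) > config.n_abstracts:
        biggest = max(title_counts, key=lambda t: title_counts[t])
        title_counts[biggest] -= 1
    for rtype, n_title in title_counts.items():
        of_type = [s for s in slots if s.rtype == rtype]
        idx = rng.permutation(len(of_type))[:n_title]
        for i in idx:
            of_type[i].section = "title"
    return slots


# ---------------------------------------------------------------------------
# sentence realization

def generate_sentence(
    rtype: str,
    rng: np.random.Generator,
    *,
    trigger: str | None = None,
    has_trigger: bool | None = None,
    negative_category: int | None = None,
    plant: tuple[str, str] | None = None,
    disease: tuple[str, str] | None = None,
    abbreviate_plant: bool = False,
) -> RealizedSentence:
    """Realize one single-pair sentence whose cues encode ``rtype``.

    ToD/CoD/Association sentences use the type's trigger lexicon (or a
    trigger-less template); Negative sentences instantiate one of the four
    negative categories (research-objective phrasing, bare co-occurrence,
    explicit no-correlation, title co-mention).
    """
    if plant is None:
        name = list(PLANTS)[rng.integers(len(PLANTS))]
        plant = (name, PLANTS[name])
    if disease is None:
        name = list(DISEASES)[rng.integers(len(DISEASES))]
        disease = (name, DISEASES[name])

    if rtype == "Negative":
        cat = negative_category or int(rng.integers(1, 4))
        template = TEMPLATES[NEGATIVE_TEMPLATES[cat]]
        return realize(
            template,
            plant=plant,
            disease=disease,
            relations=[("Negative", "plant", "disease", False)],
            negative_category=cat,
            abbreviate_plant=abbreviate_plant,
        )

    if has_trigger is None:
        has_trigger = trigger is not None
    if has_trigger:
        lexicon = TRIGGER_REALIZATIONS[rtype]
        if trigger is None:
            trigger = list(lexicon)[rng.integers(len(lexicon))]
        options = lexicon[trigger]
        template_id, t_surface, prep = options[rng.integers(len(options))]
        return realize(
            TEMPLATES[template_id],
            plant=plant,
            disease=disease,
            trigger_surface=t_surface,
            prep_surface=prep,
            trigger_rtype=rtype,
            relations=[(rtype, "plant", "disease", True)],
            abbreviate_plant=abbreviate_plant,
        )
    options = TRIGGERLESS_TEMPLATES[rtype]
    template_id = options[rng.integers(len(options))]
    return realize(
        TEMPLATES[template_id],
        plant=plant,
        disease=disease,
        relations=[(rtype, "plant", "disease", False)],
        abbreviate_plant=abbreviate_plant,
    )


def _realize_multi(
    kind: str, s1: _Slot, s2: _Slot, rng: np.random.Generator
) -> RealizedSentence:
    if kind == "multi_contrast":
        template = TEMPLATES["multi_contrast"]
        surface = TRIGGER_REALIZATIONS["ToD"][s1.trigger][0][1]
        return realize(
            template,
            plant=s1.plant,
            plant2=s2.plant,
            disease=s1.disease,
            trigger_surface=surface,
            trigger_rtype="ToD",
            relations=[
                ("ToD", "plant", "disease", True),
                ("Negative", "plant2", "disease", False),
            ],
            negative_category=3,
        )
    if kind == "multi_both":
        template = TEMPLATES["multi_both"]
        surface = TRIGGER_REALIZATIONS["ToD"][s1.trigger][0][1]
        return realize(
            template,
            plant=s1.plant,
            plant2=s2.plant,
            disease=s1.disease,
            trigger_surface=surface,
            trigger_rtype="ToD",
            relations=[
                ("ToD", "plant", "disease", True),
                ("ToD", "plant2", "disease", True),
            ],
        )
    template = TEMPLATES["multi_reviewed"]
    return realize(
        template,
        plant=s1.plant,
        plant2=s2.plant,
        disease=s1.disease,
        relations=[
            ("Negative", "plant", "disease", False),
            ("Negative", "plant2", "disease", False),
        ],
        negative_category=1,
    )


def _pairable(s1: _Slot, s2: _Slot) -> str | None:
    """Multi-pair sentence kind for two abstract slots, if any."""
    trans = set(TRANSITIVE_TOD_TRIGGERS)
    if s1.rtype == "ToD" and s1.trigger in trans and s2.rtype == "Negative":
        return "multi_contrast"
    if (
        s1.rtype == "ToD"
        and s2.rtype == "ToD"
        and s1.trigger in trans
        and s1.trigger == s2.trigger
    ):
        return "multi_both"
    if s1.rtype == "Negative" and s2.rtype == "Negative":
        return "multi_reviewed"
    return None


# ---------------------------------------------------------------------------
# document assembly

def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[list[StandoffDocument], Manifest]:
    """Generate a standoff corpus and its ground-truth manifest.

    The same seed yields a byte-identical corpus; every document passes
    structural validation and round-trips through the standoff writer.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    factor = config.n_abstracts / BASE_ABSTRACTS

    slots = _build_slots(config, rng)
    title_slots = [s for s in slots if s.section == "title"]
    abstract_slots = [s for s in slots if s.section == "abstract"]
    rng.shuffle(title_slots)
    rng.shuffle(abstract_slots)

    # deal abstract slots round-robin over documents
    doc_abstract: list[list[_Slot]] = [[] for _ in range(config.n_abstracts)]
    order = rng.permutation(config.n_abstracts)
    for i, slot in enumerate(abstract_slots):
        doc_abstract[order[i % config.n_abstracts]].append(slot)
    doc_title: list[_Slot | None] = [None] * config.n_abstracts
    title_docs = rng.permutation(config.n_abstracts)[: len(title_slots)]
    for d, slot in zip(title_docs, title_slots):
        doc_title[d] = slot

    # group abstract slots into sentences (single or multi-pair)
    doc_sentences: list[list[RealizedSentence]] = []
    stats = _Stats()
    for d in range(config.n_abstracts):
        sentences: list[RealizedSentence] = []
        pool = doc_abstract[d]
        used = [False] * len(pool)
        for i, slot in enumerate(pool):
            if used[i]:
                continue
            used[i] = True
            partner = None
            kind = None
            if rng.random() < config.multi_pair_rate:
                for j in range(i + 1, len(pool)):
                    if used[j]:
                        continue
                    kind = _pairable(slot, pool[j])
                    if kind:
                        partner = j
                        break
            if partner is not None:
                used[partner] = True
                sent = _realize_multi(kind, slot, pool[partner], rng)
                stats.multi_pair += 1
            else:
                abbrev = (
                    slot.rtype != "Negative" and rng.random() < config.equiv_rate
                )
                cat = None
                if slot.rtype == "Negative":
                    cat = int(rng.choice([1, 2, 3], p=[0.4, 0.3, 0.3]))
                sent = generate_sentence(
                    slot.rtype,
                    rng,
                    trigger=slot.trigger,
                    has_trigger=slot.has_trigger,
                    negative_category=cat,
                    plant=slot.plant,
                    disease=slot.disease,
                    abbreviate_plant=abbrev,
                )
            sentences.append(sent)
        doc_sentences.append(sentences)

    # title sentences
    title_sents: list[RealizedSentence | None] = []
    for d in range(config.n_abstracts):
        slot = doc_title[d]
        if slot is None:
            title_sents.append(None)
            continue
        cat = 4 if slot.rtype == "Negative" else None
        title_sents.append(
            generate_sentence(
                slot.rtype,
                rng,
                trigger=slot.trigger,
                has_trigger=slot.has_trigger,
                negative_category=cat,
                plant=slot.plant,
                disease=slot.disease,
            )
        )

    # sentence quotas: pad with entity-free fillers
    n_title_sent = max(config.n_abstracts, round(BASE_TITLE_SENTENCES * factor))
    extra_titles = n_title_sent - config.n_abstracts
    n_abstract_sent = round(BASE_ABSTRACT_SENTENCES * factor)
    relation_sent_total = sum(len(s) for s in doc_sentences)
    n_fillers = max(0, n_abstract_sent - relation_sent_total)
    fillers_per_doc = [n_fillers // config.n_abstracts] * config.n_abstracts
    for i in range(n_fillers % config.n_abstracts):
        fillers_per_doc[i] += 1

    docs: list[StandoffDocument] = []
    manifest = Manifest(
        n_abstracts=config.n_abstracts,
        type_counts={t: {"with": 0, "without": 0} for t in BASE_TYPE_TOTALS},
        title_relations={t: 0 for t in BASE_TYPE_TOTALS},
        abstract_relations={t: 0 for t in BASE_TYPE_TOTALS},
        title_sentences=0,
        abstract_sentences=0,
        trigger_counts={t: {} for t in BASE_TYPE_TOTALS},
        plant_counts={t: {} for t in BASE_TYPE_TOTALS},
        negative_categories={1: 0, 2: 0, 3: 0, 4: 0},
        multi_pair_sentences=stats.multi_pair,
        equiv_pairs=0,
        plant_mentions=0,
        dictionary_mentions=0,
        sentences_per_doc={},
        gold_labels=[],
        parses={},
    )

    for d in range(config.n_abstracts):
        doc_id = str(10_000_001 + d)
        title = title_sents[d]
        title_texts = [title.text if title else GENERIC_TITLES[d % len(GENERIC_TITLES)]]
        if d < extra_titles:
            title_texts.append(EXTRA_TITLE_SENTENCE)

        body = list(doc_sentences[d])
        rng.shuffle(body)
        filler_texts = [
            FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
            for _ in range(fillers_per_doc[d])
        ]
        body_items: list[RealizedSentence | str] = list(body)
        for f in filler_texts:
            body_items.insert(int(rng.integers(len(body_items) + 1)), f)

        doc = _assemble_document(doc_id, title_texts, title, body_items, manifest)
        docs.append(doc)

    return docs, manifest


@dataclass
class _Stats:
    multi_pair: int = 0


def _assemble_document(
    doc_id: str,
    title_texts: list[str],
    title_sent: RealizedSentence | None,
    body_items: Sequence[RealizedSentence | str],
    manifest: Manifest,
) -> StandoffDocument:
    """Join sentences into one text and lift sentence-local annotations to
    document offsets, updating the manifest in place."""
    pieces: list[tuple[str, RealizedSentence | None, str]] = []
    for i, t in enumerate(title_texts):
        pieces.append((t, title_sent if i == 0 and title_sent else None, "title"))
    for item in body_items:
        if isinstance(item, str):
            pieces.append((item, None, "abstract"))
        else:
            pieces.append((item.text, item, "abstract"))

    text_parts: list[str] = []
    offset = 0
    sentence_spans: list[Span] = []
    entities: list[EntityAnnotation] = []
    triggers: list[TriggerAnnotation] = []
    relations: list[RelationAnnotation] = []
    equivs: list[EquivAnnotation] = []
    e_counter = r_counter = 0
    trigger_records: list[tuple[str, Span, str]] = []

    for idx, (sent_text, realized, section) in enumerate(pieces):
        text_parts.append(sent_text)
        span = Span(offset, offset + len(sent_text))
        sentence_spans.append(span)
        manifest.title_sentences += section == "title"
        manifest.abstract_sentences += section == "abstract"

        if realized is not None:
            manifest.parses.setdefault(
                sent_text, realized.graph
            )
            role_to_id: dict[str, str] = {}
            for ent in sorted(realized.entities, key=lambda e: e.span):
                e_counter += 1
                eid = f"T{e_counter}"
                role_to_id[ent.role] = eid
                entities.append(
                    EntityAnnotation(
                        eid,
                        ent.etype,
                        Span(ent.span.start + offset, ent.span.end + offset),
                        ent.mention,
                        ent.concept_id,
                    )
                )
                if ent.etype == "Plant":
                    manifest.plant_mentions += 1
                    manifest.dictionary_mentions += ent.role != "abbrev"
            trig_id = None
            if realized.trigger is not None:
                rtype, t_span, mention = realized.trigger
                trigger_records.append(
                    (rtype, Span(t_span.start + offset, t_span.end + offset), mention)
                )
                trig_id = len(trigger_records) - 1  # resolved after entity ids
            for rtype, p_role, d_role, uses_trigger in realized.relations:
                r_counter += 1
                rid = (f"E{r_counter}" if uses_trigger else f"R{r_counter}")
                relations.append(
                    RelationAnnotation(
                        rid,
                        rtype,
                        role_to_id[p_role],
                        role_to_id[d_role],
                        f"__TRIG{trig_id}__" if uses_trigger else None,
                    )
                )
                manifest.gold_labels.append((doc_id, rid, rtype))
                bucket = "with" if uses_trigger else "without"
                manifest.type_counts[rtype][bucket] += 1
                (manifest.title_relations if section == "title" else manifest.abstract_relations)[rtype] += 1
                pc = manifest.plant_counts[rtype]
                p_concept = next(
                    e.concept_id for e in realized.entities if e.role == p_role
                )
                pc[p_concept] = pc.get(p_concept, 0) + 1
                if uses_trigger and realized.trigger is not None:
                    from ..corpus_stats import normalize_trigger

                    canon = normalize_trigger(realized.trigger[2])
                    tc = manifest.trigger_counts[rtype]
                    tc[canon] = tc.get(canon, 0) + 1
            if realized.negative_category is not None and any(
                r[0] == "Negative" for r in realized.relations
            ):
                n_neg = sum(r[0] == "Negative" for r in realized.relations)
                manifest.negative_categories[realized.negative_category] += n_neg
            for role_a, role_b in realized.equiv_roles:
                equivs.append(
                    EquivAnnotation(frozenset({role_to_id[role_a], role_to_id[role_b]}))
                )
                manifest.equiv_pairs += 1

        offset += len(sent_text)
        if idx == len(title_texts) - 1:
            text_parts.append("\n")
            offset += 1
        elif idx < len(pieces) - 1:
            text_parts.append(" ")
            offset += 1

    # triggers get ids after the last entity id; relations then reference them
    trig_ids: dict[int, str] = {}
    for i, (rtype, span, mention) in enumerate(trigger_records):
        e_counter += 1
        trig_ids[i] = f"T{e_counter}"
        triggers.append(TriggerAnnotation(f"T{e_counter}", rtype, span, mention))
    relations = [
        RelationAnnotation(
            r.id,
            r.rtype,
            r.plant_id,
            r.disease_id,
            trig_ids[int(r.trigger_id[6:-2])] if r.trigger_id else None,
        )
        for r in relations
    ]

    doc = StandoffDocument(
        doc_id=doc_id,
        text="".join(text_parts),
        entities=entities,
        triggers=triggers,
        relations=relations,
        equivs=equivs,
    ).sorted()
    manifest.sentences_per_doc[doc_id] = sentence_spans
    return doc
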
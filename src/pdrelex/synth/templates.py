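"""Sentence templates with hand-written dependency structure.

Each template is a list of (form, POS, head, deprel) tuples where ``head``
is 1-based within the template and 0 marks the root.  Slot forms ("{P}",
"{P2}", "{D}", "{T}", "{PREP}") are filled at realization time; a
multi-token filler expands with its non-final tokens attached as compounds
to its final token, so the entity head is always the last filler token.

The closed vocabulary keeps parses hand-checkable and lets the corpus
generator ship exact dependency graphs for every relation-bearing sentence,
removing any dependence on an external parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ..sdp import DependencyGraph
from ..standoff import Span

__all__ = [
    "Template",
    "RealizedSentence",
    "RealizedEntity",
    "realize",
    "TEMPLATES",
    "TRIGGER_REALIZATIONS",
    "TRANSITIVE_TOD_TRIGGERS",
    "FILLER_SENTENCES",
    "GENERIC_TITLES",
    "EXTRA_TITLE_SENTENCE",
]

Tok = tuple[str, str, int, str]  # form-or-slot, POS, head (1-based, 0=root), deprel


@dataclass(frozen=True)
class Template:
    id: str
    tokens: tuple[Tok, ...]
    # template token indices (1-based) whose realized span is the trigger mention
    trigger_tokens: tuple[int, ...] = ()


def _t(*tokens: Tok) -> tuple[Tok, ...]:
    return tuple(tokens)


TEMPLATES: dict[str, Template] = {
    t.id: t
    for t in [
        # --- ToD with trigger ---
        Template(
            "tod_trans",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("extract", "NOUN", 3, "nsubj"),
                ("{T}", "VERB", 0, "root"),
                ("{D}", "NOUN", 3, "obj"),
                ("in", "ADP", 6, "case"),
                ("patients", "NOUN", 3, "obl"),
                (".", "PUNCT", 3, "punct"),
            ),
            trigger_tokens=(3,),
        ),
        Template(
            "tod_protect",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("consumption", "NOUN", 3, "nsubj"),
                ("{T}", "VERB", 0, "root"),
                ("against", "ADP", 5, "case"),
                ("{D}", "NOUN", 3, "obl"),
                (".", "PUNCT", 3, "punct"),
            ),
            trigger_tokens=(3, 4),
        ),
        Template(
            "tod_effect",
            _t(
                ("{P}", "NOUN", 2, "nsubj"),
                ("had", "VERB", 0, "root"),
                ("a", "DET", 5, "det"),
                ("protective", "ADJ", 5, "amod"),
                ("effect", "NOUN", 2, "obj"),
                ("on", "ADP", 7, "case"),
                ("{D}", "NOUN", 5, "nmod"),
                (".", "PUNCT", 2, "punct"),
            ),
            trigger_tokens=(4, 5),
        ),
        # --- ToD without trigger ---
        Template(
            "tod_notrig_a",
            _t(
                ("Patients", "NOUN", 5, "nsubj"),
                ("with", "ADP", 3, "case"),
                ("{D}", "NOUN", 1, "nmod"),
                ("were", "AUX", 5, "aux"),
                ("given", "VERB", 0, "root"),
                ("{P}", "NOUN", 7, "compound"),
                ("supplementation", "NOUN", 5, "obj"),
                ("daily", "ADV", 5, "advmod"),
                (".", "PUNCT", 5, "punct"),
            ),
        ),
        Template(
            "tod_notrig_b",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("preparations", "NOUN", 4, "nsubj"),
                ("were", "AUX", 4, "aux"),
                ("administered", "VERB", 0, "root"),
                ("to", "ADP", 6, "case"),
                ("subjects", "NOUN", 4, "obl"),
                ("with", "ADP", 8, "case"),
                ("{D}", "NOUN", 6, "nmod"),
                (".", "PUNCT", 4, "punct"),
            ),
        ),
        # --- CoD with trigger ---
        Template(
            "cod_trans",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("exposure", "NOUN", 3, "nsubj"),
                ("{T}", "VERB", 0, "root"),
                ("{D}", "NOUN", 3, "obj"),
                ("in", "ADP", 6, "case"),
                ("adults", "NOUN", 3, "obl"),
                (".", "PUNCT", 3, "punct"),
            ),
            trigger_tokens=(3,),
        ),
        Template(
            "cod_increase",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("consumption", "NOUN", 3, "nsubj"),
                ("{T}", "VERB", 0, "root"),
                ("the", "DET", 5, "det"),
                ("risk", "NOUN", 3, "obj"),
                ("of", "ADP", 7, "case"),
                ("{D}", "NOUN", 5, "nmod"),
                (".", "PUNCT", 3, "punct"),
            ),
            trigger_tokens=(3,),
        ),
        Template(
            "cod_risk",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("consumption", "NOUN", 3, "nsubj"),
                ("{T}", "VERB", 0, "root"),
                ("the", "DET", 5, "det"),
                ("risk", "NOUN", 3, "obj"),
                ("of", "ADP", 7, "case"),
                ("{D}", "NOUN", 5, "nmod"),
                (".", "PUNCT", 3, "punct"),
            ),
            trigger_tokens=(3, 4, 5, 6),
        ),
        Template(
            "cod_assoc",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("exposure", "NOUN", 4, "nsubj"),
                ("was", "AUX", 4, "aux"),
                ("{T}", "VERB", 0, "root"),
                ("{PREP}", "ADP", 7, "case"),
                ("elevated", "ADJ", 7, "amod"),
                ("rates", "NOUN", 4, "obl"),
                ("of", "ADP", 9, "case"),
                ("{D}", "NOUN", 7, "nmod"),
                (".", "PUNCT", 4, "punct"),
            ),
            trigger_tokens=(4, 5),
        ),
        # --- CoD without trigger ---
        Template(
            "cod_notrig",
            _t(
                ("Heavy", "ADJ", 3, "amod"),
                ("{P}", "NOUN", 3, "compound"),
                ("users", "NOUN", 4, "nsubj"),
                ("developed", "VERB", 0, "root"),
                ("{D}", "NOUN", 4, "obj"),
                ("over", "ADP", 7, "case"),
                ("time", "NOUN", 4, "obl"),
                (".", "PUNCT", 4, "punct"),
            ),
        ),
        # --- Association with trigger ---
        Template(
            "assoc_noun",
            _t(
                ("A", "DET", 3, "det"),
                ("significant", "ADJ", 3, "amod"),
                ("association", "NOUN", 9, "nsubj"),
                ("between", "ADP", 5, "case"),
                ("{P}", "NOUN", 3, "nmod"),
                ("and", "CCONJ", 7, "cc"),
                ("{D}", "NOUN", 5, "conj"),
                ("was", "AUX", 9, "aux"),
                ("observed", "VERB", 0, "root"),
                (".", "PUNCT", 9, "punct"),
            ),
            trigger_tokens=(3,),
        ),
        Template(
            "assoc_verb",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("intake", "NOUN", 4, "nsubj"),
                ("was", "AUX", 4, "aux"),
                ("{T}", "VERB", 0, "root"),
                ("{PREP}", "ADP", 6, "case"),
                ("{D}", "NOUN", 4, "obl"),
                ("in", "ADP", 9, "case"),
                ("several", "DET", 9, "det"),
                ("cohorts", "NOUN", 4, "obl"),
                (".", "PUNCT", 4, "punct"),
            ),
            trigger_tokens=(4, 5),
        ),
        Template(
            "assoc_influence",
            _t(
                ("{P}", "NOUN", 3, "nsubj"),
                ("may", "AUX", 3, "aux"),
                ("{T}", "VERB", 0, "root"),
                ("{D}", "NOUN", 5, "compound"),
                ("progression", "NOUN", 3, "obj"),
                (".", "PUNCT", 3, "punct"),
            ),
            trigger_tokens=(3,),
        ),
        Template(
            "assoc_effect",
            _t(
                ("{P}", "NOUN", 2, "nsubj"),
                ("exerted", "VERB", 0, "root"),
                ("measurable", "ADJ", 4, "amod"),
                ("effects", "NOUN", 2, "obj"),
                ("on", "ADP", 6, "case"),
                ("{D}", "NOUN", 4, "nmod"),
                (".", "PUNCT", 2, "punct"),
            ),
            trigger_tokens=(4,),
        ),
        # --- Association without trigger ---
        Template(
            "assoc_notrig",
            _t(
                ("The", "DET", 2, "det"),
                ("interplay", "NOUN", 7, "nsubj"),
                ("between", "ADP", 4, "case"),
                ("{P}", "NOUN", 2, "nmod"),
                ("and", "CCONJ", 6, "cc"),
                ("{D}", "NOUN", 4, "conj"),
                ("appeared", "VERB", 0, "root"),
                ("complex", "ADJ", 7, "xcomp"),
                (".", "PUNCT", 7, "punct"),
            ),
        ),
        # --- Negative categories (1) co-occurrence, (2) objective/hypothesis,
        # (3) no correlation found, (4) title co-mention ---
        Template(
            "neg_cooccur",
            _t(
                ("{D}", "NOUN", 2, "compound"),
                ("biomarkers", "NOUN", 7, "nsubj"),
                ("and", "CCONJ", 5, "cc"),
                ("{P}", "NOUN", 5, "compound"),
                ("metabolites", "NOUN", 2, "conj"),
                ("were", "AUX", 7, "aux"),
                ("measured", "VERB", 0, "root"),
                ("in", "ADP", 9, "case"),
                ("serum", "NOUN", 7, "obl"),
                (".", "PUNCT", 7, "punct"),
            ),
        ),
        Template(
            "neg_objective",
            _t(
                ("We", "PRON", 2, "nsubj"),
                ("aimed", "VERB", 0, "root"),
                ("to", "PART", 4, "mark"),
                ("investigate", "VERB", 2, "xcomp"),
                ("whether", "SCONJ", 7, "mark"),
                ("{P}", "NOUN", 7, "nsubj"),
                ("affects", "VERB", 4, "ccomp"),
                ("{D}", "NOUN", 7, "obj"),
                (".", "PUNCT", 2, "punct"),
            ),
        ),
        Template(
            "neg_nocorr",
            _t(
                ("No", "DET", 3, "det"),
                ("significant", "ADJ", 3, "amod"),
                ("correlation", "NOUN", 9, "nsubj"),
                ("between", "ADP", 5, "case"),
                ("{P}", "NOUN", 3, "nmod"),
                ("and", "CCONJ", 7, "cc"),
                ("{D}", "NOUN", 5, "conj"),
                ("was", "AUX", 9, "aux"),
                ("detected", "VERB", 0, "root"),
                (".", "PUNCT", 9, "punct"),
            ),
        ),
        Template(
            "neg_title",
            _t(
                ("{P}", "NOUN", 2, "compound"),
                ("consumption", "NOUN", 0, "root"),
                ("and", "CCONJ", 4, "cc"),
                ("{D}", "NOUN", 2, "conj"),
                ("in", "ADP", 8, "case"),
                ("a", "DET", 8, "det"),
                ("prospective", "ADJ", 8, "amod"),
                ("cohort", "NOUN", 2, "nmod"),
                (".", "PUNCT", 2, "punct"),
            ),
        ),
        # --- multi-pair sentences ---
        Template(
            "multi_contrast",  # pair 1: ToD with trigger; pair 2: Negative (3)
            _t(
                ("{P}", "NOUN", 5, "nsubj"),
                ("but", "CCONJ", 4, "cc"),
                ("not", "PART", 4, "advmod"),
                ("{P2}", "NOUN", 1, "conj"),
                ("{T}", "VERB", 0, "root"),
                ("{D}", "NOUN", 5, "obj"),
                (".", "PUNCT", 5, "punct"),
            ),
            trigger_tokens=(5,),
        ),
        Template(
            "multi_both",  # both pairs: ToD with the same trigger
            _t(
                ("Both", "CCONJ", 2, "cc"),
                ("{P}", "NOUN", 5, "nsubj"),
                ("and", "CCONJ", 4, "cc"),
                ("{P2}", "NOUN", 2, "conj"),
                ("{T}", "VERB", 0, "root"),
                ("{D}", "NOUN", 5, "obj"),
                (".", "PUNCT", 5, "punct"),
            ),
            trigger_tokens=(5,),
        ),
        Template(
            "multi_reviewed",  # both pairs: Negative (1)
            _t(
                ("{P}", "NOUN", 5, "nsubj"),
                ("and", "CCONJ", 3, "cc"),
                ("{P2}", "NOUN", 1, "conj"),
                ("were", "AUX", 5, "aux"),
                ("reviewed", "VERB", 0, "root"),
                ("alongside", "ADP", 7, "case"),
                ("{D}", "NOUN", 5, "obl"),
                (".", "PUNCT", 5, "punct"),
            ),
        ),
    ]
}

# canonical trigger -> (template id, {T} surface, {PREP} surface or None)
TRANSITIVE_TOD_TRIGGERS = (
    "reduce", "decrease", "prevent", "inhibit", "attenuate", "ameliorate",
    "improve", "treat",
)


def _past(verb: str) -> str:
    return verb + "d" if verb.endswith("e") else verb + "ed"


TRIGGER_REALIZATIONS: dict[str, dict[str, list[tuple[str, str | None, str | None]]]] = {
    "ToD": {
        **{t: [("tod_trans", _past(t), None)] for t in TRANSITIVE_TOD_TRIGGERS},
        "protect": [("tod_protect", "protected", None)],
        "effect": [("tod_effect", None, None)],
    },
    "CoD": {
        "induce": [("cod_trans", "induced", None)],
        "cause": [("cod_trans", "caused", None)],
        "promote": [("cod_trans", "promoted", None)],
        "exacerbate": [("cod_trans", "exacerbated", None)],
        "provoke": [("cod_trans", "provoked", None)],
        "aggravate": [("cod_trans", "aggravated", None)],
        "increase": [("cod_increase", "increased", None)],
        "risk": [("cod_risk", "increased", None)],
        "relate": [("cod_assoc", "related", "to")],
        "associate": [("cod_assoc", "associated", "with")],
    },
    "Association": {
        "associate": [("assoc_noun", None, None), ("assoc_verb", "associated", "with")],
        "relate": [("assoc_verb", "related", "to")],
        "influence": [("assoc_influence", "influence", None)],
        "effect": [("assoc_effect", None, None)],
    },
}

TRIGGERLESS_TEMPLATES = {
    "ToD": ("tod_notrig_a", "tod_notrig_b"),
    "CoD": ("cod_notrig",),
    "Association": ("assoc_notrig",),
}

NEGATIVE_TEMPLATES = {1: "neg_cooccur", 2: "neg_objective", 3: "neg_nocorr", 4: "neg_title"}

FILLER_SENTENCES = (
    "The assay was repeated three times .",
    "Samples were stored at low temperature .",
    "Baseline characteristics were comparable across groups .",
    "Data were analyzed with standard software .",
    "Participants completed the questionnaire at follow-up .",
    "The protocol was approved by the review board .",
)

GENERIC_TITLES = (
    "A laboratory study of dietary compounds .",
    "An observational analysis of nutritional habits .",
    "A methodological note on survey design .",
)

EXTRA_TITLE_SENTENCE = "A registry analysis ."


@dataclass(frozen=True)
class RealizedEntity:
    role: str  # "plant" | "plant2" | "disease" | "abbrev"
    etype: str  # "Plant" | "Disease"
    span: Span  # sentence-local character span
    mention: str
    concept_id: str


@dataclass
class RealizedSentence:
    """One generated sentence with sentence-local annotation structure."""

    text: str
    graph: DependencyGraph  # offsets aligned to ``text``
    entities: list[RealizedEntity]
    trigger: tuple[str, Span, str] | None  # (rtype, span, mention)
    # (rtype, plant role, disease role, uses_trigger)
    relations: list[tuple[str, str, str, bool]]
    equiv_roles: list[tuple[str, str]] = field(default_factory=list)
    negative_category: int | None = None
    template_id: str = ""


def realize(
    template: Template,
    *,
    plant: tuple[str, str],
    disease: tuple[str, str],
    plant2: tuple[str, str] | None = None,
    trigger_surface: str | None = None,
    prep_surface: str | None = None,
    trigger_rtype: str | None = None,
    relations: Sequence[tuple[str, str, str, bool]],
    abbreviate_plant: bool = False,
    negative_category: int | None = None,
) -> RealizedSentence:
    """Fill a template's slots and build its text, graph, and annotations.

    Multi-token slot fillers expand compound-first; ``abbreviate_plant``
    appends "( ABBR )" after the plant with an appositive abbreviation
    entity sharing the plant's concept id.
    """
    slot_fill = {
        "{P}": plant[0].split(),
        "{D}": disease[0].split(),
    }
    if plant2 is not None:
        slot_fill["{P2}"] = plant2[0].split()
    if trigger_surface is not None:
        slot_fill["{T}"] = [trigger_surface]
    if prep_surface is not None:
        slot_fill["{PREP}"] = [prep_surface]

    forms: list[str] = []
    pos: list[str] = []
    head_of: list[int | None] = []  # final index of each token's head; None = root
    rels: list[str] = []
    final_of_template: dict[int, int] = {}  # template 1-based idx -> final head-token idx
    pending_heads: list[int] = []  # template head (1-based) per final token, 0 root
    slot_token_ranges: dict[str, tuple[int, int]] = {}

    for t_idx, (form, p, head, rel) in enumerate(template.tokens, start=1):
        if form in slot_fill:
            pieces = slot_fill[form]
            start = len(forms)
            for piece in pieces[:-1]:
                forms.append(piece)
                pos.append("NOUN")
                pending_heads.append(-1)  # placeholder: compound to slot head
                rels.append("compound")
            forms.append(pieces[-1])
            pos.append(p)
            pending_heads.append(head)
            rels.append(rel)
            final_of_template[t_idx] = len(forms) - 1
            # wire the compound placeholders to the slot head
            for j in range(start, len(forms) - 1):
                pending_heads[j] = -2 - (len(forms) - 1)  # encode final index
            slot_token_ranges[form] = (start, len(forms))
        else:
            forms.append(form)
            pos.append(p)
            pending_heads.append(head)
            rels.append(rel)
            final_of_template[t_idx] = len(forms) - 1

    heads: list[int] = []
    for ph in pending_heads:
        if ph == 0:
            heads.append(-1)
        elif ph <= -2:
            heads.append(-ph - 2)
        else:
            heads.append(final_of_template[ph])

    # optional abbreviation after the plant slot
    equiv_roles: list[tuple[str, str]] = []
    abbrev_range: tuple[int, int] | None = None
    if abbreviate_plant:
        p_start, p_end = slot_token_ranges["{P}"]
        plant_head = p_end - 1
        abbr = plant[0].replace(" ", "")[:3].upper() + "X"  # never a dictionary name
        insert_at = p_end
        extra = [("(", "PUNCT", plant_head, "punct"), (abbr, "NOUN", plant_head, "appos"), (")", "PUNCT", plant_head, "punct")]
        for off, (f, pp, h, r) in enumerate(extra):
            forms.insert(insert_at + off, f)
            pos.insert(insert_at + off, pp)
            rels.insert(insert_at + off, r)
        heads = [h if h < insert_at else h + 3 for h in heads]
        for off, (f, pp, h, r) in enumerate(extra):
            heads.insert(insert_at + off, h)
        final_of_template = {
            k: (v if v < insert_at else v + 3) for k, v in final_of_template.items()
        }
        slot_token_ranges = {
            k: (s if s < insert_at else s + 3, e if e <= insert_at else e + 3)
            for k, (s, e) in slot_token_ranges.items()
        }
        abbrev_range = (insert_at + 1, insert_at + 2)
        equiv_roles.append(("plant", "abbrev"))

    text = " ".join(forms)
    offsets = []
    cursor = 0
    for form in forms:
        offsets.append((cursor, cursor + len(form)))
        cursor += len(form) + 1
    graph = DependencyGraph(
        tuple(forms), tuple(pos), tuple(heads), tuple(rels), tuple(offsets)
    )

    def entity(role: str, etype: str, rng: tuple[int, int], concept: str) -> RealizedEntity:
        span = Span(offsets[rng[0]][0], offsets[rng[1] - 1][1])
        return RealizedEntity(role, etype, span, text[span.start : span.end], concept)

    entities = [
        entity("plant", "Plant", slot_token_ranges["{P}"], plant[1]),
        entity("disease", "Disease", slot_token_ranges["{D}"], disease[1]),
    ]
    if plant2 is not None:
        entities.append(entity("plant2", "Plant", slot_token_ranges["{P2}"], plant2[1]))
    if abbrev_range is not None:
        entities.append(entity("abbrev", "Plant", abbrev_range, plant[1]))

    trigger = None
    if template.trigger_tokens and trigger_rtype is not None:
        t_indices = [final_of_template[i] for i in template.trigger_tokens]
        t_span = Span(offsets[min(t_indices)][0], offsets[max(t_indices)][1])
        trigger = (trigger_rtype, t_span, text[t_span.start : t_span.end])

    return RealizedSentence(
        text=text,
        graph=graph,
        entities=entities,
        trigger=trigger,
        relations=list(relations),
        equiv_roles=equiv_roles,
        negative_category=negative_category,
        template_id=template.id,
    )
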
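"""Standoff parsing, writing, validation, and the flat relation table."""

import pandas as pd
import pytest

from pdrelex import standoff
from pdrelex.standoff import (
    EntityAnnotation,
    RelationAnnotation,
    Span,
    StandoffDocument,
    StandoffParseError,
    StandoffValidationError,
    TriggerAnnotation,
    parse_document,
    parse_flat_table,
    validate_document,
    write_document,
)

TXT = (
    "Coffee consumption was recently shown to protect against "
    "symptomatic gallbladder disease."
)


class TestParse:
    def test_entity_with_taxonomy_normalization(self):
        a1 = "T1\tPlant 0 6\tCoffee\nN1\tReference T1\tTaxonomy:13443\n"
        doc = parse_document(TXT, a1, "", doc_id="11117612")
        assert len(doc.entities) == 1
        ent = doc.entities[0]
        assert (ent.etype, ent.span, ent.mention) == ("Plant", Span(0, 6), "Coffee")
        assert ent.concept_id == "13443"

    def test_lenient_trailing_concept_column(self):
        doc = parse_document(TXT, "T1\tPlant 0 6\tCoffee\t13443\n", "")
        assert doc.entities[0].concept_id == "13443"

    def test_empty_annotation_files(self):
        doc = parse_document(TXT, "", "")
        assert doc.text == TXT
        assert not doc.entities and not doc.triggers and not doc.relations

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(StandoffParseError, match="line 2"):
            parse_document(TXT, "T1\tPlant 0 6\tCoffee\nbroken line\n", "")

    def test_unknown_line_type_not_silently_dropped(self):
        with pytest.raises(StandoffParseError, match="unknown"):
            parse_document(TXT, "X1\tPlant 0 6\tCoffee\n", "")

    def test_mention_text_mismatch_names_offender(self):
        with pytest.raises(StandoffValidationError, match="T1"):
            parse_document(TXT, "T1\tPlant 0 6\tNotCoffee\n", "")


class TestWrite:
    def _doc(self, with_trigger: bool) -> StandoffDocument:
        text = "Peppermint oil reduced headache in patients.\nBody text here."
        entities = [
            EntityAnnotation("T1", "Plant", Span(0, 10), "Peppermint", "34256"),
            EntityAnnotation("T2", "Disease", Span(23, 31), "headache", "D006261"),
        ]
        if with_trigger:
            triggers = [TriggerAnnotation("T3", "ToD", Span(15, 22), "reduced")]
            relations = [RelationAnnotation("E1", "ToD", "T1", "T2", "T3")]
        else:
            triggers = []
            relations = [RelationAnnotation("R1", "CoD", "T1", "T2", None)]
        return StandoffDocument("1", text, entities, triggers, relations)

    def test_triggered_relation_emits_trigger_and_event_line(self):
        _, _, a2 = write_document(self._doc(with_trigger=True))
        lines = a2.strip().split("\n")
        assert lines[0] == "T3\tToD 15 22\treduced"
        assert lines[1] == "E1\tToD:T3 Cause:T1 Theme:T2"

    def test_triggerless_relation_has_no_trigger_reference(self):
        _, _, a2 = write_document(self._doc(with_trigger=False))
        assert a2.strip() == "R1\tCoD Arg1:T1 Arg2:T2"

    def test_write_is_deterministic(self):
        doc = self._doc(with_trigger=True)
        assert write_document(doc) == write_document(doc)

    def test_refuses_invalid_document(self):
        doc = self._doc(with_trigger=False)
        doc.entities[0] = EntityAnnotation("T1", "Plant", Span(0, 10), "WRONG-TEXT", None)
        with pytest.raises(StandoffValidationError):
            write_document(doc)


def test_round_trip_on_generated_documents(default_corpus):
    """parse(write(doc)) == doc for 100 generated documents."""
    docs, _ = default_corpus
    for doc in docs[:100]:
        txt, a1, a2 = write_document(doc)
        assert parse_document(txt, a1, a2, doc.doc_id) == doc


class TestValidate:
    def _base(self) -> StandoffDocument:
        return StandoffDocument(
            "1",
            "Garlic reduced cancer.\nMore text.",
            entities=[
                EntityAnnotation("T1", "Plant", Span(0, 6), "Garlic", "4682"),
                EntityAnnotation("T2", "Disease", Span(15, 21), "cancer", "D009369"),
            ],
        )

    def test_compliant_document_has_no_violations(self):
        doc = self._base()
        doc.relations.append(RelationAnnotation("R1", "ToD", "T1", "T2"))
        assert validate_document(doc) == []

    def test_arg_type_violation_when_arg1_is_disease(self):
        doc = self._base()
        doc.relations.append(RelationAnnotation("R1", "ToD", "T2", "T1"))
        codes = {v.code for v in validate_document(doc)}
        assert "arg-type" in codes

    def test_negative_relation_with_trigger_flagged(self):
        doc = self._base()
        doc.triggers.append(TriggerAnnotation("T3", "ToD", Span(7, 14), "reduced"))
        doc.relations.append(RelationAnnotation("E1", "Negative", "T1", "T2", "T3"))
        codes = {v.code for v in validate_document(doc)}
        assert "negative-with-trigger" in codes

    def test_span_beyond_text_end(self):
        doc = self._base()
        doc.entities.append(EntityAnnotation("T9", "Plant", Span(300, 310), "ghost", None))
        codes = {v.code for v in validate_document(doc)}
        assert "span-bounds" in codes

    def test_cross_sentence_relation_flagged(self):
        doc = self._base()
        doc.relations.append(RelationAnnotation("R1", "ToD", "T1", "T2"))
        # a segmentation that separates the two entities
        sentences = [Span(0, 10), Span(11, 33)]
        codes = {v.code for v in validate_document(doc, sentences)}
        assert "cross-sentence" in codes

    def test_validation_is_monotone_under_added_annotations(self):
        doc = self._base()
        doc.relations.append(RelationAnnotation("R1", "ToD", "T2", "T1"))
        before = set(map(str, validate_document(doc)))
        doc.entities.append(EntityAnnotation("T9", "Plant", Span(300, 310), "ghost", None))
        after = set(map(str, validate_document(doc)))
        assert before <= after


class TestFlatTable:
    def test_category_and_trigger_mapping(self):
        records = parse_flat_table(
            [
                {
                    "PMID": "20021021",
                    "plant mention": "peppermint",
                    "disease indication": "headache",
                    "relation category": "ToD",
                    "trigger mention": "reduced",
                }
            ]
        )
        assert len(records) == 1
        assert records[0].category == "ToD"
        assert records[0].trigger == "reduced"

    def test_empty_table(self):
        frame = pd.DataFrame(columns=["pmid", "plant", "disease", "category"])
        assert parse_flat_table(frame) == []

    def test_unknown_category_names_row(self):
        with pytest.raises(standoff.FlatTableError, match="row 0"):
            parse_flat_table(
                [
                    {
                        "pmid": "1",
                        "plant": "tea",
                        "disease": "cancer",
                        "category": "mystery",
                    }
                ]
            )

    def test_generated_table_round_trips_record_count(self, small_corpus):
        from pdrelex import candidates

        docs, _ = small_corpus
        rows = []
        for doc in docs:
            if len(rows) >= 25:
                break
            sentences = candidates.split_sentences(doc.text)
            rows.extend(standoff.flat_records(doc, sentences))
        frame = pd.DataFrame([r.__dict__ for r in rows[:25]])
        assert len(parse_flat_table(frame)) == 25
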
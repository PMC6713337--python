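"""Corpus statistics: type counts, trigger normalization/coverage, rankings."""

import pytest

from pdrelex import candidates
from pdrelex.corpus_stats import (
    concept_frequency,
    normalize_trigger,
    relation_type_counts,
    relations_per_abstract,
    section_stats,
    top_k_trigger_coverage,
    trigger_counts,
)
from pdrelex.standoff import (
    EntityAnnotation,
    RelationAnnotation,
    Span,
    StandoffDocument,
    TriggerAnnotation,
)


def tiny_doc(doc_id="1"):
    text = "Garlic reduced cancer and tobacco was discussed.\nFiller text."
    return StandoffDocument(
        doc_id,
        text,
        entities=[
            EntityAnnotation("T1", "Plant", Span(0, 6), "Garlic", "4682"),
            EntityAnnotation("T2", "Disease", Span(15, 21), "cancer", "D009369"),
            EntityAnnotation("T3", "Plant", Span(26, 33), "tobacco", "4097"),
        ],
        triggers=[TriggerAnnotation("T4", "ToD", Span(7, 14), "reduced")],
        relations=[
            RelationAnnotation("E1", "ToD", "T1", "T2", "T4"),
            RelationAnnotation("R2", "Negative", "T3", "T2", None),
        ],
    )


class TestNormalizeTrigger:
    @pytest.mark.parametrize(
        "mention, expected",
        [
            ("reduced", "reduce"),
            ("reducing", "reduce"),
            ("Reduces", "reduce"),
            ("associated with", "associate"),
            ("related to", "relate"),
            ("effect", "effect"),
            ("effects", "effect"),
            ("protective effect", "effect"),
            ("protected against", "protect"),
            ("increased the risk of", "risk"),
            ("association", "associate"),
            ("prevented", "prevent"),
            ("induces", "induce"),
            ("risk", "risk"),
        ],
    )
    def test_canonical_forms(self, mention, expected):
        assert normalize_trigger(mention) == expected

    def test_empty_mention_rejected(self):
        with pytest.raises(ValueError):
            normalize_trigger("   ")


class TestRelationTypeCounts:
    def test_tiny_corpus(self):
        counts = relation_type_counts([tiny_doc()])
        assert counts.with_trigger["ToD"] == 1
        assert counts.without_trigger["Negative"] == 1
        assert counts.positive_total == 1
        assert counts.grand_total == 2

    def test_empty_corpus_all_zero(self):
        counts = relation_type_counts([])
        assert counts.grand_total == 0

    def test_generated_corpus_recovers_manifest(self, small_corpus):
        docs, manifest = small_corpus
        counts = relation_type_counts(docs)
        for rtype, split in manifest.type_counts.items():
            assert counts.with_trigger[rtype] == split["with"]
            assert counts.without_trigger[rtype] == split["without"]
        assert counts.grand_total == manifest.total_relations


class TestTriggerCoverage:
    def test_generated_trigger_counts_match_manifest(self, small_corpus):
        docs, manifest = small_corpus
        for rtype in ("ToD", "CoD", "Association"):
            assert dict(trigger_counts(docs, rtype)) == manifest.trigger_counts[rtype]

    def test_monotone_in_k_and_bounded(self, small_corpus):
        docs, _ = small_corpus
        values = [top_k_trigger_coverage(docs, "ToD", k) for k in range(1, 12)]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] <= 100.0

    def test_k_beyond_distinct_triggers_is_total(self, small_corpus):
        docs, _ = small_corpus
        assert top_k_trigger_coverage(docs, "ToD", 1000) == pytest.approx(100.0)

    def test_no_triggers_rejected(self):
        with pytest.raises(ValueError):
            top_k_trigger_coverage([tiny_doc()], "CoD", 5)


class TestConceptFrequency:
    def test_single_relation_ranking(self):
        ranking = concept_frequency([tiny_doc()], "Plant", "ToD")
        assert ranking.entries == (("garlic", "4682", 1),)

    def test_absent_disease_filter_empty(self):
        ranking = concept_frequency([tiny_doc()], "Plant", disease_filter="D000000")
        assert ranking.entries == ()

    def test_generated_counts_match_manifest(self, small_corpus):
        docs, manifest = small_corpus
        for rtype in ("ToD", "CoD", "Negative"):
            ranking = concept_frequency(docs, "Plant", rtype)
            got = {cid: n for _, cid, n in ranking.entries}
            assert got == manifest.plant_counts[rtype]

    def test_counts_sum_to_relations_of_type(self, small_corpus):
        docs, manifest = small_corpus
        ranking = concept_frequency(docs, "Plant", "CoD")
        split = manifest.type_counts["CoD"]
        assert sum(n for _, _, n in ranking.entries) == split["with"] + split["without"]

    def test_counts_non_increasing(self, small_corpus):
        docs, _ = small_corpus
        entries = concept_frequency(docs, "Plant", "Negative").entries
        counts = [n for _, _, n in entries]
        assert counts == sorted(counts, reverse=True)


class TestSections:
    def test_generated_corpus_section_totals(self, small_corpus):
        docs, manifest = small_corpus
        sentences = {d.doc_id: candidates.split_sentences(d.text) for d in docs}
        stats = section_stats(docs, sentences)
        assert stats["title"].sentences == manifest.title_sentences
        assert stats["abstract"].sentences == manifest.abstract_sentences
        assert stats["title"].relations == sum(manifest.title_relations.values())
        assert stats["abstract"].relations == sum(manifest.abstract_relations.values())
        for rtype, n in manifest.title_relations.items():
            assert stats["title"].by_type[rtype] == n

    def test_zero_relation_section_is_zero_percent(self):
        doc = StandoffDocument("1", "A title.\nA body sentence.")
        sentences = {"1": candidates.split_sentences(doc.text)}
        stats = section_stats([doc], sentences)
        assert stats["title"].relation_rate == 0.0
        assert stats["title"].type_percentage("ToD") == 0.0


class TestRelationsPerAbstract:
    def test_direct_division(self):
        docs = [tiny_doc(str(i)) for i in range(4)]
        docs[0].relations += [
            RelationAnnotation("R3", "Negative", "T3", "T2", None),
            RelationAnnotation("R4", "Negative", "T1", "T2", None),
        ]
        assert relations_per_abstract(docs) == 2.5

    def test_no_relations_is_zero(self):
        assert relations_per_abstract([StandoffDocument("1", "text")]) == 0.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            relations_per_abstract([])
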
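"""Dependency graphs, shortest dependency paths, and instance features."""

import networkx as nx
import numpy as np
import pytest

from pdrelex.candidates import CandidatePair, split_sentences
from pdrelex.sdp import (
    DependencyGraph,
    build_instance,
    featurize_corpus,
    insert_position_indicators,
    merge_entity_tokens,
    position_indices,
    shortest_dependency_path,
)
from pdrelex.standoff import EntityAnnotation, Span
from pdrelex.synth import TemplateParserAdapter

from conftest import FIG_SENTENCE


class TestDependencyGraph:
    def test_conllu_round_trip(self, fig_graph):
        again = DependencyGraph.from_conllu(fig_graph.to_conllu())
        assert again.tokens == fig_graph.tokens
        assert again.heads == fig_graph.heads

    def test_rejects_multiple_roots(self):
        with pytest.raises(ValueError, match="root"):
            DependencyGraph(("a", "b"), ("X", "X"), (-1, -1), ("root", "root"))

    def test_rejects_cycles(self):
        with pytest.raises(ValueError):
            DependencyGraph(
                ("a", "b", "c"), ("X",) * 3, (1, 2, 1), ("d",) * 3
            )


class TestMergeEntityTokens:
    def test_two_token_entity_collapses_to_one_node(self, fig_graph):
        merged, node = merge_entity_tokens(fig_graph, (9, 11))
        assert len(merged) == len(fig_graph) - 1
        assert merged.tokens[node] == "gallbladder disease"
        # the merged node keeps the range's syntactic head link (to "symptomatic")
        assert merged.heads[node] == 8

    def test_single_token_entity_is_identity(self, fig_graph):
        merged, node = merge_entity_tokens(fig_graph, (0, 1))
        assert merged is fig_graph and node == 0

    def test_node_count_decreases_by_range_length_minus_one(self, fig_graph):
        for lo, hi in [(9, 11), (2, 5)]:
            merged, _ = merge_entity_tokens(fig_graph, (lo, hi))
            assert len(merged) == len(fig_graph) - (hi - lo - 1)

    def test_bad_range_rejected(self, fig_graph):
        with pytest.raises(ValueError):
            merge_entity_tokens(fig_graph, (5, 5))


class TestShortestDependencyPath:
    def test_worked_example_subpaths(self, fig_graph):
        """The coffee/gallbladder-disease sentence splits at 'protect'."""
        merged, disease_node = merge_entity_tokens(fig_graph, (9, 11))
        result = shortest_dependency_path(merged, 0, disease_node)
        left = [merged.tokens[i] for i in result.left]
        right = [merged.tokens[i] for i in result.right]
        assert left == ["Coffee", "consumption", "protect"]
        assert right == ["protect", "against", "symptomatic", "gallbladder disease"]

    def test_direct_governance_single_edge(self):
        # e1 governs e2: left is just the plant, right spans the edge
        g = DependencyGraph(
            ("coffee", "gallstones"),
            ("NOUN", "NOUN"),
            (-1, 0),
            ("root", "nmod"),
        )
        res = shortest_dependency_path(g, 0, 1)
        assert res.left == (0,)
        assert res.right == (0, 1)

    def test_reverse_governance_single_edge(self):
        # e2 governs e1: the disease is the split node
        g = DependencyGraph(
            ("coffee", "gallstones"),
            ("NOUN", "NOUN"),
            (1, -1),
            ("nmod", "root"),
        )
        res = shortest_dependency_path(g, 0, 1)
        assert res.left == (0, 1)
        assert res.right == (1,)

    def test_subpaths_share_exactly_one_node(self, fig_graph):
        res = shortest_dependency_path(fig_graph, 0, 10)
        assert res.left[-1] == res.right[0]
        assert len(set(res.left) & set(res.right)) == 1

    def test_matches_exhaustive_enumeration_on_random_trees(self, rng):
        """Path length equals brute-force minimum over all simple paths."""
        for _ in range(200):
            n = int(rng.integers(3, 13))
            heads = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
            g = DependencyGraph(
                tuple(f"w{i}" for i in range(n)),
                ("X",) * n,
                tuple(heads),
                ("dep",) * n,
            )
            a, b = rng.choice(n, size=2, replace=False)
            res = shortest_dependency_path(g, int(a), int(b))
            ug = g.to_undirected()
            best = min(
                len(p) for p in nx.all_simple_paths(ug, int(a), int(b))
            )
            assert len(res.path) == best
            assert res.path[0] == a and res.path[-1] == b
            # split node dominates both halves: edges descend away from it
            split = res.left[-1]
            assert split == res.right[0]


class TestPositionIndicators:
    def test_worked_sentence_tagging(self, fig_graph):
        tokens = insert_position_indicators(fig_graph.tokens, (0, 1), (9, 11))
        assert tokens[0] == "e1start" and tokens[2] == "e1end"
        assert tokens[-4] == "e2start" and tokens[-1] == "e2end"
        assert len(tokens) == len(fig_graph.tokens) + 4
        assert " ".join(tokens) == (
            "e1start Coffee e1end consumption was recently shown to protect "
            "against symptomatic e2start gallbladder disease e2end"
        )

    def test_entity_at_sequence_start(self):
        tokens = insert_position_indicators(("a", "b", "c"), (0, 1), (2, 3))
        assert tokens[0] == "e1start"

    def test_length_invariant_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 15))
            lo1 = int(rng.integers(0, n - 3))
            hi1 = lo1 + 1
            lo2 = int(rng.integers(hi1, n - 1))
            hi2 = lo2 + 1
            out = insert_position_indicators(tuple("t" * n), (lo1, hi1), (lo2, hi2))
            assert len(out) == n + 4

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            insert_position_indicators(("a", "b"), (0, 2), (1, 2))


class TestPositionIndices:
    def test_zero_inside_entity_and_unit_neighbours(self):
        p1, _ = position_indices(5, (2, 3), (4, 5), clip=30)
        assert p1[2] == 30  # offset 0 shifted by clip
        assert p1[1] == 29  # immediately left: -1
        assert p1[3] == 31  # immediately right: +1

    def test_clipping(self):
        p1, _ = position_indices(80, (0, 1), (1, 2), clip=30)
        assert p1[-1] == 60  # +clip, shifted
        p1b, _ = position_indices(80, (79, 80), (1, 2), clip=30)
        assert p1b[0] == 0  # -clip, shifted


class TestBuildInstance:
    def pair(self):
        return CandidatePair(
            "doc",
            Span(0, len(FIG_SENTENCE)),
            EntityAnnotation("T1", "Plant", Span(0, 6), "Coffee", "13443"),
            EntityAnnotation(
                "T2", "Disease", Span(69, 88), "gallbladder disease", "D005705"
            ),
        )

    def test_worked_example_sdp_lengths(self, fig_graph):
        inst = build_instance(FIG_SENTENCE, self.pair(), lambda s: fig_graph, "ToD")
        assert not inst.no_sdp
        assert len(inst.left_tokens) == 3
        assert len(inst.right_tokens) == 4
        assert inst.left_tokens[0] == "Coffee"
        assert inst.right_tokens[-1] == "gallbladder disease"
        assert len(inst.tokens) == len(inst.p1_indices) == len(inst.p2_indices)
        assert len(inst.tokens) == len(fig_graph.tokens) + 4

    def test_deterministic(self, fig_graph):
        a = build_instance(FIG_SENTENCE, self.pair(), lambda s: fig_graph, "ToD")
        b = build_instance(FIG_SENTENCE, self.pair(), lambda s: fig_graph, "ToD")
        assert a == b

    def test_parse_failure_flags_instance(self):
        def failing_parser(s):
            raise ValueError("no parse")

        inst = build_instance(FIG_SENTENCE, self.pair(), failing_parser, "ToD")
        assert inst.no_sdp and inst.sdp is None


def test_mean_sdp_distance_below_mean_linear_distance(small_instances):
    """Dependency paths shorten the plant-disease distance on average."""
    linear = np.mean([i.meta["linear_distance"] for i in small_instances])
    sdp_d = np.mean([i.meta["sdp_distance"] for i in small_instances])
    assert sdp_d <= linear


def test_featurize_corpus_builds_one_instance_per_relation(small_corpus, small_instances):
    docs, manifest = small_corpus
    assert len(small_instances) == manifest.total_relations
    assert all(not i.no_sdp for i in small_instances)
    labels = sorted({i.label for i in small_instances})
    assert labels == ["Association", "CoD", "Negative", "ToD"]
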
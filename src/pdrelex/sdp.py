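"""Dependency graphs, shortest dependency paths, and instance features.

The classifier consumes, per candidate plant-disease pair, three token
sequences: the sentence with position-indicator tags (``e1start``/``e1end``
around the plant, ``e2start``/``e2end`` around the disease) and the two
halves of the shortest dependency path (SDP) between the entities.  The SDP
is computed on the dependency tree after collapsing each multi-token entity
into a single node, and is split at the node where edge direction flips --
the node that dominates both remaining halves.  Both subpaths include that
split node, e.g. for "Coffee consumption was recently shown to protect
against symptomatic gallbladder disease":

    left  = Coffee -> consumption -> protect
    right = protect <- against <- symptomatic <- gallbladder disease

Each token additionally carries two relative-position indices (signed token
distance to the plant and to the disease, clipped) and a POS tag.

Dependency parses enter through a pluggable adapter: any callable mapping a
sentence string to a :class:`DependencyGraph`.  No parser is bundled; the
synthetic corpus generator provides template parses, and tests use
hand-transcribed fixture graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import networkx as nx

from .candidates import CandidatePair
from .standoff import Span, StandoffDocument

__all__ = [
    "DependencyGraph",
    "SDPResult",
    "RelationInstance",
    "ParserAdapter",
    "merge_entity_tokens",
    "shortest_dependency_path",
    "insert_position_indicators",
    "position_indices",
    "build_instance",
    "featurize_corpus",
]

ParserAdapter = Callable[[str], "DependencyGraph"]

INDICATOR_POS = "IND"
DEFAULT_POSITION_CLIP = 30


@dataclass(frozen=True)
class DependencyGraph:
    """A parsed sentence: one head per token, exactly one root, acyclic.

    ``heads`` holds 0-based head indices with -1 marking the root.
    ``offsets`` optionally aligns tokens to character offsets in the source
    sentence (needed to map entity spans onto token ranges).
    """

    tokens: tuple[str, ...]
    pos_tags: tuple[str, ...]
    heads: tuple[int, ...]
    deprels: tuple[str, ...]
    offsets: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (len(self.pos_tags) == len(self.heads) == len(self.deprels) == n):
            raise ValueError("token/pos/head/deprel lengths differ")
        roots = [i for i, h in enumerate(self.heads) if h < 0]
        if len(roots) != 1:
            raise ValueError(f"need exactly one root, found {len(roots)}")
        for i, h in enumerate(self.heads):
            if h >= n or h == i:
                raise ValueError(f"head of token {i} out of range")
        # acyclicity: following heads from any token must reach the root
        for i in range(n):
            seen = set()
            j = i
            while self.heads[j] >= 0:
                if j in seen:
                    raise ValueError("dependency graph contains a cycle")
                seen.add(j)
                j = self.heads[j]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def root(self) -> int:
        return next(i for i, h in enumerate(self.heads) if h < 0)

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        g.add_edges_from((i, h) for i, h in enumerate(self.heads) if h >= 0)
        return g

    @classmethod
    def from_conllu(cls, text: str) -> "DependencyGraph":
        """Read CoNLL-U-style columns ID, FORM, UPOS, HEAD, DEPREL."""
        tokens, pos, heads, rels = [], [], [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"need 5 columns (ID FORM UPOS HEAD DEPREL): {line!r}")
            tokens.append(cols[1])
            pos.append(cols[2])
            heads.append(int(cols[3]) - 1)  # CoNLL-U heads are 1-based, 0 = root
            rels.append(cols[4])
        return cls(tuple(tokens), tuple(pos), tuple(heads), tuple(rels))

    def to_conllu(self) -> str:
        return "".join(
            f"{i + 1}\t{t}\t{p}\t{h + 1}\t{r}\n"
            for i, (t, p, h, r) in enumerate(
                zip(self.tokens, self.pos_tags, self.heads, self.deprels)
            )
        )

    def align_to_text(self, text: str) -> "DependencyGraph":
        """Attach character offsets by greedy left-to-right token matching."""
        offsets = []
        pos = 0
        for tok in self.tokens:
            idx = text.find(tok, pos)
            if idx < 0:
                raise ValueError(f"token {tok!r} not found in text")
            offsets.append((idx, idx + len(tok)))
            pos = idx + len(tok)
        return replace(self, offsets=tuple(offsets))

    def token_range_for_span(self, span: Span) -> tuple[int, int]:
        """Contiguous token range (start, end exclusive) covered by a span."""
        if self.offsets is None:
            raise ValueError("graph has no character offsets; call align_to_text")
        covered = [
            i for i, (s, e) in enumerate(self.offsets) if s < span.end and span.start < e
        ]
        if not covered:
            raise ValueError(f"no tokens overlap span {span}")
        lo, hi = covered[0], covered[-1] + 1
        if covered != list(range(lo, hi)):
            raise ValueError(f"span {span} covers non-contiguous tokens")
        return lo, hi


@dataclass(frozen=True)
class SDPResult:
    """Left/right SDP halves as token indices; both contain the split node."""

    left: tuple[int, ...]  # plant node .. split node
    right: tuple[int, ...]  # split node .. disease node

    @property
    def split_node(self) -> int:
        return self.left[-1]

    @property
    def path(self) -> tuple[int, ...]:
        """Full path without the duplicated split node."""
        return self.left + self.right[1:]


@dataclass
class RelationInstance:
    """Featurized candidate: sentence channel + two SDP channels + label."""

    doc_id: str
    tokens: tuple[str, ...]  # indicator-augmented sentence, length i
    pos_tags: tuple[str, ...]
    p1_indices: tuple[int, ...]  # clipped signed offsets to the plant, shifted >= 0
    p2_indices: tuple[int, ...]
    sdp: SDPResult | None  # indices into the merged (pre-indicator) tokenization
    left_tokens: tuple[str, ...] = ()
    left_pos: tuple[str, ...] = ()
    left_p1: tuple[int, ...] = ()
    left_p2: tuple[int, ...] = ()
    right_tokens: tuple[str, ...] = ()
    right_pos: tuple[str, ...] = ()
    right_p1: tuple[int, ...] = ()
    right_p2: tuple[int, ...] = ()
    label: str | None = None
    no_sdp: bool = False
    meta: dict = field(default_factory=dict)


def merge_entity_tokens(
    graph: DependencyGraph, token_range: tuple[int, int]
) -> tuple[DependencyGraph, int]:
    """Collapse a contiguous multi-token entity into a single node.

    The merged node keeps the head of the range's syntactic head (the token
    whose head lies outside the range; fallback: the last token), and its
    surface form is the space-joined range.  Returns the new graph and the
    merged node's index.  A single-token range returns the graph unchanged.
    """
    lo, hi = token_range
    if not (0 <= lo < hi <= len(graph)):
        raise ValueError(f"bad token range {token_range}")
    if hi - lo == 1:
        return graph, lo

    head_tok = next(
        (i for i in range(lo, hi) if not (lo <= graph.heads[i] < hi)), hi - 1
    )

    def new_index(old: int) -> int:
        if lo <= old < hi:
            return lo
        return old if old < lo else old - (hi - lo - 1)

    tokens, pos, heads, rels, offs = [], [], [], [], []
    for i in range(len(graph)):
        if lo <= i < hi and i != head_tok:
            continue
        if i == head_tok:
            tokens.append(" ".join(graph.tokens[lo:hi]))
            if graph.offsets is not None:
                offs.append((graph.offsets[lo][0], graph.offsets[hi - 1][1]))
        else:
            tokens.append(graph.tokens[i])
            if graph.offsets is not None:
                offs.append(graph.offsets[i])
        pos.append(graph.pos_tags[i])
        h = graph.heads[i]
        heads.append(h if h < 0 else new_index(h))
        rels.append(graph.deprels[i])
    merged = DependencyGraph(
        tuple(tokens),
        tuple(pos),
        tuple(heads),
        tuple(rels),
        tuple(offs) if graph.offsets is not None else None,
    )
    return merged, lo


def shortest_dependency_path(
    graph: DependencyGraph, plant_node: int, disease_node: int
) -> SDPResult:
    """Minimal undirected path between the entity nodes, split where edge
    direction flips.

    Walking from the plant, edges first ascend head links and then descend;
    the split node is where the ascent ends (the path node dominating both
    halves).  When one entity dominates the other, that entity itself is the
    split node and the corresponding half is the single-node path.  Ties are
    broken toward the plant side.
    """
    n = len(graph)
    if not (0 <= plant_node < n and 0 <= disease_node < n):
        raise ValueError("entity node out of range")
    try:
        path = nx.shortest_path(graph.to_undirected(), plant_node, disease_node)
    except nx.NetworkXNoPath as exc:  # pragma: no cover - trees are connected
        raise ValueError("entities are disconnected in the dependency graph") from exc

    split_pos = len(path) - 1  # default: all edges ascend (disease dominates)
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        if graph.heads[b] == a:  # descending edge: a dominates b
            split_pos = i
            break
    return SDPResult(tuple(path[: split_pos + 1]), tuple(path[split_pos:]))


def insert_position_indicators(
    tokens: Sequence[str],
    plant_range: tuple[int, int],
    disease_range: tuple[int, int],
) -> tuple[str, ...]:
    """Wrap the entity token ranges in e1start/e1end and e2start/e2end tags."""
    (p_lo, p_hi), (d_lo, d_hi) = plant_range, disease_range
    if p_lo < d_hi and d_lo < p_hi:
        raise ValueError("entity ranges overlap")
    inserts = sorted(
        [(p_lo, "e1start"), (p_hi, "e1end"), (d_lo, "e2start"), (d_hi, "e2end")],
        key=lambda x: x[0],
        reverse=True,
    )
    out = list(tokens)
    for pos, tag in inserts:
        out.insert(pos, tag)
    return tuple(out)


def position_indices(
    n_tokens: int,
    plant_range: tuple[int, int],
    disease_range: tuple[int, int],
    clip: int = DEFAULT_POSITION_CLIP,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Signed token offsets to the nearest token of each entity, clipped to
    [-clip, clip] and shifted by +clip so indices are non-negative."""

    def stream(lo: int, hi: int) -> tuple[int, ...]:
        out = []
        for i in range(n_tokens):
            if i < lo:
                off = i - lo
            elif i >= hi:
                off = i - (hi - 1)
            else:
                off = 0
            out.append(max(-clip, min(clip, off)) + clip)
        return tuple(out)

    return stream(*plant_range), stream(*disease_range)


def build_instance(
    sentence_text: str,
    pair: CandidatePair,
    parser: ParserAdapter,
    label: str | None = None,
    clip: int = DEFAULT_POSITION_CLIP,
) -> RelationInstance:
    """Featurize one candidate pair.

    The sentence channel is the indicator-augmented original tokenization;
    the SDP channels come from the entity-merged graph.  If the sentence
    cannot be parsed or the entities cannot be aligned, the instance is
    flagged ``no_sdp`` (such instances are excluded from SDP-CNN training).
    """
    sent_off = pair.sentence.start
    plant_span = Span(pair.plant.span.start - sent_off, pair.plant.span.end - sent_off)
    disease_span = Span(
        pair.disease.span.start - sent_off, pair.disease.span.end - sent_off
    )
    try:
        graph = parser(sentence_text)
        if graph is None:
            raise ValueError("parser returned no graph")
        if graph.offsets is None:
            graph = graph.align_to_text(sentence_text)
        p_range = graph.token_range_for_span(plant_span)
        d_range = graph.token_range_for_span(disease_span)
    except ValueError:
        return RelationInstance(
            doc_id=pair.doc_id,
            tokens=(),
            pos_tags=(),
            p1_indices=(),
            p2_indices=(),
            sdp=None,
            label=label,
            no_sdp=True,
        )

    # sentence channel on the original tokenization
    aug_tokens = insert_position_indicators(graph.tokens, p_range, d_range)
    aug_p_range, aug_d_range = _augmented_ranges(p_range, d_range)
    aug_pos = _augmented_pos(graph.pos_tags, p_range, d_range)
    p1, p2 = position_indices(len(aug_tokens), aug_p_range, aug_d_range, clip)

    # SDP channels on the entity-merged graph; merge the later range first so
    # the earlier one keeps its indices
    first, second = sorted([p_range, d_range])
    merged, _ = merge_entity_tokens(graph, second)
    merged, first_node = merge_entity_tokens(merged, (first[0], first[1]))
    second_node = second[0] - (first[1] - first[0] - 1)
    plant_node, disease_node = (
        (first_node, second_node) if first == p_range else (second_node, first_node)
    )
    sdp = shortest_dependency_path(merged, plant_node, disease_node)
    m_p1, m_p2 = position_indices(
        len(merged), (plant_node, plant_node + 1), (disease_node, disease_node + 1), clip
    )

    def channel(ids: tuple[int, ...]):
        return (
            tuple(merged.tokens[i] for i in ids),
            tuple(merged.pos_tags[i] for i in ids),
            tuple(m_p1[i] for i in ids),
            tuple(m_p2[i] for i in ids),
        )

    lt, lp, lp1, lp2 = channel(sdp.left)
    rt, rp, rp1, rp2 = channel(sdp.right)
    return RelationInstance(
        doc_id=pair.doc_id,
        tokens=aug_tokens,
        pos_tags=aug_pos,
        p1_indices=p1,
        p2_indices=p2,
        sdp=sdp,
        left_tokens=lt,
        left_pos=lp,
        left_p1=lp1,
        left_p2=lp2,
        right_tokens=rt,
        right_pos=rp,
        right_p1=rp1,
        right_p2=rp2,
        label=label,
        meta={
            # both distances in hops over the merged tokenization: adjacent
            # tokens are 1 apart linearly, adjacent path nodes 1 apart on SDP
            "linear_distance": abs(plant_node - disease_node),
            "sdp_distance": len(sdp.path) - 1,
        },
    )


def _augmented_ranges(
    p_range: tuple[int, int], d_range: tuple[int, int]
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Entity token ranges after indicator insertion (each entity +1 from its
    own start tag, +2 more for every earlier entity's tags)."""

    def shift(r: tuple[int, int], other: tuple[int, int]) -> tuple[int, int]:
        delta = 1 + (2 if other[1] <= r[0] else 0)
        return (r[0] + delta, r[1] + delta)

    return shift(p_range, d_range), shift(d_range, p_range)


def _augmented_pos(
    pos_tags: Sequence[str], p_range: tuple[int, int], d_range: tuple[int, int]
) -> tuple[str, ...]:
    inserts = sorted([p_range[0], p_range[1], d_range[0], d_range[1]], reverse=True)
    out = list(pos_tags)
    for pos in inserts:
        out.insert(pos, INDICATOR_POS)
    return tuple(out)


def featurize_corpus(
    docs: Sequence[StandoffDocument],
    parser: ParserAdapter,
    sentences_per_doc: dict[str, Sequence[Span]],
    clip: int = DEFAULT_POSITION_CLIP,
    drop_no_sdp: bool = True,
) -> list[RelationInstance]:
    """Build one instance per annotated relation across a corpus."""
    instances = []
    for doc in docs:
        ents = doc.entity_by_id()
        sentences = sentences_per_doc[doc.doc_id]
        for r in doc.relations:
            plant, disease = ents[r.plant_id], ents[r.disease_id]
            sent = next(
                (
                    s
                    for s in sentences
                    if s.contains(plant.span) and s.contains(disease.span)
                ),
                None,
            )
            if sent is None:
                continue
            pair = CandidatePair(doc.doc_id, sent, plant, disease)
            inst = build_instance(
                doc.text[sent.start : sent.end], pair, parser, label=r.rtype, clip=clip
            )
            if inst.no_sdp and drop_no_sdp:
                continue
            instances.append(inst)
    return instances
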
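# Methods

## Scope and data model

The package operates on standoff-annotated abstracts: a `.txt` file whose
first line is the title, a `.a1` file with typed entity spans (Plant with
NCBI Taxonomy ids, Disease with MEDIC ids — MeSH `D`/`C` or OMIM), and a
`.a2` file with relation-type triggers, relations, and Equiv lines.
Offsets are 0-based and end-exclusive over the raw text including the
newline after the title.  Concept ids travel on separate normalization
lines (`N1<TAB>Reference T1<TAB>Taxonomy:13443`); the reader also accepts
a trailing tab-separated id column on entity lines.  Relations with a
trigger are written as event lines (`E1<TAB>ToD:T9 Cause:T1 Theme:T2`),
trigger-less relations as `R1<TAB>CoD Arg1:T1 Arg2:T2`.  These two forms
preserve the distinction that drives the with/without-trigger statistics.

Structural validation is deliberately machine-checkable only: span
bounds, mention/text agreement, argument typing (Arg1 Plant, Arg2
Disease), trigger/relation type agreement, the no-trigger rule for
Negative relations, Equiv type homogeneity, and — when a sentence
segmentation is supplied — the same-sentence constraint.  Judgement
calls made by human annotators (e.g. whether a mention is "really" a
disease) are out of scope.

## Agreement metrics

For a k-category confusion matrix between two annotators (rows =
annotator 2) with N units:

- simple index `P0 = trace/N`;
- chance agreement `Pe = (1/N²) Σ_k n_k1 n_k2` from the two marginals;
- `κ = 1 − (1−P0)/(1−Pe)` (undefined at Pe = 1, reported as such);
- `G = 1 − (1−P0)/(1−Pk)` with `Pk = 1/k`.

G and κ coincide exactly when `Pe = 1/k`; G exceeds κ when marginals are
skewed (`Pe > 1/k`).  Both properties are property-tested on random
matrices.  Span-level agreement (entities, triggers) pairs units greedily
left-to-right, each unit at most once, with strict (identical span and
type) or soft (overlapping span, same type) matching and denominator
`max(|A|,|B|)`; the pairing rule and denominator are our choice, since
only the strict/soft distinction is standard.

## Trigger normalization

Triggers are short verb or noun phrases.  Normalization lowercases,
strips trailing prepositions, and lemmatizes the remaining head (last)
word with suffix rules plus a small exception lexicon for stems that
restore a final "e" ("reduced" → "reduce") and for noun/verb pairs
("association" → "associate").  A full lemmatizer is unnecessary at this
vocabulary size and would add a parser-scale dependency.

## Dictionary NER and candidates

Plant tagging is dictionary-based: case-insensitive, token-boundary,
leftmost-longest matching with a stoplist for hazardous taxonomy synonyms
("anemia", "lens", "laser", "NAME", "thymus").  All-uppercase names of at
most 4 characters require an exact-case hit, since such entries are
acronyms that otherwise fire on ordinary words.  Disease annotations are
consumed from PubTator-style offset files rather than recomputed.
Candidate relation pairs are the full plant × disease Cartesian product
within each sentence, ordered by offsets.  Sentence splitting is
rule-based (sentence-final punctuation + newlines, never merging across
the title newline); it is exact on the generator's output and adequate
for Medline-style prose.

## SDP features

Dependency parses enter through an adapter (`Callable[[str],
DependencyGraph]`); no parser is bundled.  Multi-token entities are first
collapsed into single nodes whose head is the range's syntactic head
(the token whose head lies outside the range; fallback: last token).
The SDP is the unique undirected path between the entity nodes in the
dependency tree, split at the node where edge direction flips — the node
dominating both halves — and that split node is included in both
subpaths.  When one entity dominates the other, the dominating entity is
itself the split node and one subpath degenerates to a single node.  An
exhaustive all-simple-paths enumeration over random trees serves as the
test oracle.

The sentence channel keeps the original tokenization with
`e1start/e1end/e2start/e2end` indicator tokens inserted (POS tag `IND`).
Every token carries two position indices — signed distance to the nearest
token of each entity, clipped to ±30 (configurable) and shifted to be
non-negative — and a POS id.  SDP channels are built the same way from
the merged tokenization.  Sentences that cannot be parsed or aligned
yield instances flagged `no_sdp`, which are excluded from training.

## SDP-CNN

Defaults follow the reference configuration: filter windows 3/4/5 with
100 feature maps each (separate filter banks per channel — filter
sharing across channels is not specified anywhere, and unshared banks
let sentence and path channels specialize), max-over-time pooling,
dropout 0.5, softmax over 4 labels.  Word vectors are 200-dimensional
(300 supported) and may be loaded from textual word2vec files; "static"
mode freezes them.  Position and POS embeddings default to 10 dimensions.
Choices the reference configuration leaves open are fixed as: Adam at
learning rate 1e-3, mini-batch 32, ReLU filter activations, uniform
(−0.25, 0.25) embedding init, unknown tokens mapped to a trained UNK row,
sequences shorter than the largest window padded to window length, and
optional early stopping on a validation split (patience 3).  The whole
network is numpy with hand-derived gradients; given the corpus scale
(~10³ instances, sentences ≤ ~25 tokens) this trains in seconds per fold
on one CPU and keeps the package dependency-light.  All randomness (init,
dropout, batch order, fold assignment) derives from explicit seeds, so
runs are bit-reproducible.

Cross-validation partitions *abstracts*, not instances, into k
near-equal folds (sizes differ by ≤1), preventing leakage between train
and test sentences from one abstract.  Per-fold vocabularies are built
from training data only.  Binary experiments relabel the four classes
into Positive/Negative given a positive-class set; relabelling is
idempotent.

## Evaluation

Micro precision = recall = F1 = accuracy for single-label multiclass
output; macro scores are unweighted means over the label set L.  Classes
absent from both truth and prediction contribute 0 by default
(configurable to be skipped) — the averaging convention is stated because
published macro numbers depend on it.  scikit-learn is used in the test
suite as an independent cross-check, never as the implementation.

## Synthetic corpus generator

The generator emulates the annotated corpus' composition, which **is**
its default configuration: 1,309 relations over 199 abstracts
(ToD/CoD/Association/Negative = 508/183/34/584; trigger-bearing 432/157/32),
145 title relations over 202 title sentences and the rest over 1,950
abstract sentences, per-type trigger frequency tables headed by
effect/reduce/prevent/protect/decrease (ToD) and
relate/associate/induce/increase/risk (CoD), and per-type plant-concept
tables headed by tobacco (116 of 183 CoD relations).  Tail entries of the
trigger and plant tables (needed to reach the per-type totals) are chosen
with counts strictly below the 5th-ranked entry so top-5 statistics are
stable.  Other corpus sizes scale all tables by largest-remainder
allocation; `exact_composition=False` switches to multinomial sampling of
relation types.  Defaults `multi_pair_rate=0.10` and `equiv_rate=0.05`
keep multi-pair sentences and abbreviation pairs present but minor, in
line with their rarity in real abstracts.

Sentences come from a closed set of templates with hand-written
dependency structure, so the generator ships an exact parse for every
relation-bearing sentence and the model pipeline never needs an external
parser.  Lexical cues encode the label deterministically (e.g. ToD
templates use ToD triggers; negatives instantiate one of four
sub-categories: bare co-occurrence, research-objective phrasing, explicit
no-correlation, title co-mention).  Multi-pair sentences
("X but not Y reduced Z") give two pairs with different labels in one
sentence, which only position-aware features can separate.  What the
generator does **not** emulate: open-vocabulary paraphrase, parser noise,
ambiguous cues, discontinuous or overlapping entities, and co-reference
beyond local abbreviation.  Passing tests therefore demonstrate pipeline
correctness and the model's capacity to exploit lexical/structural cues,
not expected accuracy on real Medline text.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down models
(32-dim word vectors, 8-dim position/POS embeddings, 32 filters per
window, 6 epochs) — ample for the synthetic cue-recovery task, where
10-fold micro F1 reaches ≈0.999 on a 500-abstract corpus.  Ties in
argmax predictions resolve to the lowest label index; top-k trigger
selection breaks count ties by insertion order (made irrelevant in the
generator by construction); concept rankings break count ties
lexicographically.  Degenerate inputs are signalled explicitly: κ at
Pe = 1, metrics on empty sets, G with k < 2, single-class training data.

## Known limitations

- The standoff dialect for concept ids (normalization lines) is one
  defensible reading of the format; the lenient reader covers the common
  alternative (trailing id column).
- `span_agreement`'s greedy pairing can differ from optimal matching on
  pathological overlap patterns.
- The rule-based lemmatizer covers the trigger domain, not general
  English.
- No pretrained vectors ship with the package; random init is the
  default and a word2vec text file can be supplied.
- MeSH-tree disease filtering (e.g. neoplasm subtrees) requires a
  user-supplied id → tree-number map.
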
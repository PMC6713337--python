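"""Shared fixtures: generated corpora and the worked SDP example graph."""

from __future__ import annotations

import numpy as np
import pytest

from pdrelex.sdp import DependencyGraph
from pdrelex.synth import GeneratorConfig, TemplateParserAdapter, generate_corpus

# Hand-transcribed dependency tree for the worked shortest-path example
# sentence; the tree is wired so the undirected entity path runs
# Coffee -> consumption -> protect -> against -> symptomatic -> disease.
FIG_SENTENCE = (
    "Coffee consumption was recently shown to protect against "
    "symptomatic gallbladder disease"
)
FIG_CONLLU = """\
1\tCoffee\tNOUN\t2\tcompound
2\tconsumption\tNOUN\t7\tnsubj
3\twas\tAUX\t5\taux
4\trecently\tADV\t5\tadvmod
5\tshown\tVERB\t0\troot
6\tto\tPART\t7\tmark
7\tprotect\tVERB\t5\txcomp
8\tagainst\tADP\t7\tcase
9\tsymptomatic\tADJ\t8\tamod
10\tgallbladder\tNOUN\t11\tcompound
11\tdisease\tNOUN\t9\tnmod
"""


@pytest.fixture(scope="session")
def fig_graph() -> DependencyGraph:
    return DependencyGraph.from_conllu(FIG_CONLLU).align_to_text(FIG_SENTENCE)


@pytest.fixture(scope="session")
def small_corpus():
    """40 generated abstracts plus manifest (about 260 relations)."""
    return generate_corpus(GeneratorConfig(n_abstracts=40, seed=7))


@pytest.fixture(scope="session")
def default_corpus():
    """The full default study conditions: 199 abstracts, 1309 relations."""
    return generate_corpus(GeneratorConfig())


@pytest.fixture(scope="session")
def small_instances(small_corpus):
    from pdrelex import candidates, sdp

    docs, manifest = small_corpus
    parser = TemplateParserAdapter(manifest.parses)
    sentences = {d.doc_id: candidates.split_sentences(d.text) for d in docs}
    return sdp.featurize_corpus(docs, parser, sentences)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
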
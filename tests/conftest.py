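import random

import pytest

from aee.corpus import (
    Corpus,
    DependencyEdge,
    Document,
    Entity,
    Interaction,
    SentenceGraph,
    Token,
)


def make_sentence(
    words,
    pos=None,
    edges=(),
    entities=(),
    interactions=(),
    sent_id="d0.s0",
):
    """Build a SentenceGraph from plain words and (gov, dep, rel) tuples."""
    pos = pos or ["NN"] * len(words)
    tokens = []
    cursor = 0
    for i, w in enumerate(words):
        tokens.append(
            Token(index=i, text=w, pos=pos[i], char_start=cursor, char_end=cursor + len(w))
        )
        cursor += len(w) + 1
    return SentenceGraph(
        id=sent_id,
        text=" ".join(words),
        tokens=tokens,
        edges=[DependencyEdge(governor=g, dependent=d, relation=r) for g, d, r in edges],
        entities=list(entities),
        interactions=list(interactions),
    )


def random_tree_sentence(rng: random.Random, n: int) -> SentenceGraph:
    """Random (not necessarily projective) dependency tree over n tokens."""
    words = ["w%d" % rng.randint(0, 30) for _ in range(n)]
    edges = [
        (rng.randrange(dep), dep, rng.choice(["nsubj", "dobj", "nmod", "amod"]))
        for dep in range(1, n)
    ]
    return make_sentence(words, edges=edges, sent_id="r.s0")


@pytest.fixture
def chain_sentence():
    """0-1-2 chain: NFAT1 <-nsubj- involves -dobj-> IL-4."""
    return make_sentence(
        ["NFAT1", "involves", "IL-4"],
        pos=["NN", "VBZ", "NN"],
        edges=[(1, 0, "nsubj"), (1, 2, "dobj")],
        entities=[
            Entity(id="e0", type="Protein", head=0, given=True),
            Entity(id="e1", type="Regulation", head=1, given=False),
            Entity(id="e2", type="Protein", head=2, given=True),
        ],
        interactions=[
            Interaction(id="i0", from_entity="e1", to_entity="e2", type="Theme"),
            Interaction(id="i1", from_entity="e1", to_entity="e0", type="Cause"),
        ],
    )


@pytest.fixture
def tiny_corpus(chain_sentence):
    return Corpus(id="tiny", documents=[Document(id="d0", sentences=[chain_sentence])])


TINY_XML = """\
<corpus id="tiny">
  <document id="d0">
    <sentence id="d0.s0" text="NFAT1 involves">
      <token id="t0" text="NFAT1" POS="NN" charOffset="0-5"/>
      <token id="t1" text="involves" POS="VBZ" charOffset="6-14"/>
      <dependency t1="t1" t2="t0" type="nsubj"/>
      <entity id="e0" type="Protein" headOffset="0-5" given="True"/>
    </sentence>
  </document>
</corpus>
"""


@pytest.fixture
def tiny_xml():
    return TINY_XML
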
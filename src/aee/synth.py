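"""Synthetic stand-off corpora with planted class-discriminative signal.

The generator emulates the structure of an annotated event-extraction
corpus: documents of sentences, random token strings with POS tags, a
random projective dependency tree per sentence, given protein entities,
event trigger tokens, and Theme/Cause interactions from triggers to other
entities.

The class signal is planted in *character trigrams*: each of the nine event
classes owns a signature 3-gram (built from rare letters, absent from the
background vocabulary), and a trigger token of that class contains the
signature with probability ``signal_strength``.  Full token surfaces are
randomised around the signature, so bag-of-words and stem features see
mostly unique strings while character n-gram content features carry the
generalising signal.  POS tags give a weak secondary trigger-vs-negative
cue (triggers skew verbal), and with small probability a class-specific
context word appears elsewhere in the sentence (weak sentence-level cue).

Everything is driven by one seed; the same configuration and seed yield a
byte-identical corpus.
"""

from __future__ import annotations

import math
import random
import string
from dataclasses import dataclass, field, replace

from .corpus import (
    EVENT_TYPES,
    NEGATIVE_LABEL,
    Corpus,
    DependencyEdge,
    Document,
    Entity,
    Interaction,
    SentenceGraph,
    Token,
)

#: signature character trigram per event class (rare letters, no collisions
#: with the background vocabulary, which excludes q/x/z)
SIGNATURES: dict[str, str] = {
    "Gene_expression": "qgx",
    "Transcription": "qtz",
    "Protein_catabolism": "qcx",
    "Localization": "qlz",
    "Binding": "qbx",
    "Phosphorylation": "qpz",
    "Regulation": "qrx",
    "Positive_regulation": "qvz",
    "Negative_regulation": "qnx",
}

#: sentence-level context word per event class (weak secondary signal);
#: none contains a signature trigram, so no class signal leaks into the
#: content features of these (negative) tokens
CONTEXT_WORDS: dict[str, str] = {
    "Gene_expression": "ctxgene",
    "Transcription": "ctxtran",
    "Protein_catabolism": "ctxprot",
    "Localization": "ctxloca",
    "Binding": "ctxbind",
    "Phosphorylation": "ctxphos",
    "Regulation": "ctxregu",
    "Positive_regulation": "ctxposi",
    "Negative_regulation": "ctxnega",
}

_BACKGROUND_LETTERS = "abcdefghijklmnoprstuvwy"  # no q/x/z
_RELATIONS = ("nsubj", "dobj", "nmod", "amod", "det", "prep", "conj", "advmod")
_BACKGROUND_POS = (("NN", 0.45), ("JJ", 0.15), ("DT", 0.15), ("IN", 0.15), ("RB", 0.10))
_TRIGGER_POS = (("VBZ", 0.6), ("NN", 0.4))


def _default_priors() -> dict[str, float]:
    priors = {cls: 0.02 for cls in EVENT_TYPES}
    priors[NEGATIVE_LABEL] = 1.0 - sum(priors.values())
    return priors


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic corpus.

    Defaults give roughly 200 sentences (40 documents x 5 sentences) with
    18% trigger tokens spread evenly over the nine event classes and a
    planted-signal strength of 0.8.
    """

    n_documents: int = 40
    sentences_per_doc: tuple[int, int] = (5, 5)
    tokens_per_sentence: tuple[int, int] = (6, 12)
    priors: dict[str, float] = field(default_factory=_default_priors)
    signal_strength: float = 0.8
    context_word_prob: float = 0.2
    protein_prob: float = 0.15
    vocab_size: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.n_documents < 1 or self.vocab_size < 1:
            raise ValueError("all counts must be >= 1")
        for lo, hi in (self.sentences_per_doc, self.tokens_per_sentence):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be 1 <= lo <= hi")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        total = sum(self.priors.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class priors must sum to 1 (got {total})")
        if any(p < 0 for p in self.priors.values()):
            raise ValueError("class priors must be nonnegative")
        unknown = set(self.priors) - set(EVENT_TYPES) - {NEGATIVE_LABEL}
        if unknown:
            raise ValueError(f"unknown classes in priors: {unknown}")


def _weighted_choice(rng: random.Random, pairs) -> str:
    r = rng.random()
    acc = 0.0
    for value, weight in pairs:
        acc += weight
        if r < acc:
            return value
    return pairs[-1][0]


def _make_vocab(rng: random.Random, size: int) -> list[str]:
    vocab: set[str] = set()
    while len(vocab) < size:
        length = rng.randint(3, 8)
        vocab.add("".join(rng.choice(_BACKGROUND_LETTERS) for _ in range(length)))
    return sorted(vocab)


def _protein_name(rng: random.Random) -> str:
    stem = "".join(rng.choice(string.ascii_uppercase) for _ in range(rng.randint(2, 4)))
    if rng.random() < 0.5:
        return f"{stem}-{rng.randint(1, 9)}"
    return f"{stem}{rng.randint(1, 9)}"


def _plant_signature(rng: random.Random, word: str, signature: str) -> str:
    pos = rng.randint(0, len(word))
    return word[:pos] + signature + word[pos:]


def _projective_edges(rng: random.Random, n: int) -> list[tuple[int, int]]:
    """Random projective dependency tree: each subtree spans an interval."""
    edges: list[tuple[int, int]] = []

    def build(lo: int, hi: int, parent: int | None) -> None:
        if lo > hi:
            return
        root = rng.randint(lo, hi)
        if parent is not None:
            edges.append((parent, root))
        build(lo, root - 1, root)
        build(root + 1, hi, root)

    build(0, n - 1, None)
    return edges


def _generate_sentence(
    rng: random.Random, sent_id: str, vocab: list[str], config: SynthConfig
) -> SentenceGraph:
    n = rng.randint(*config.tokens_per_sentence)
    priors = sorted(config.priors.items())
    labels = [_weighted_choice(rng, priors) for _ in range(n)]
    words: list[str] = []
    pos_tags: list[str] = []
    is_protein = [False] * n
    for i, label in enumerate(labels):
        if label == NEGATIVE_LABEL:
            if rng.random() < config.protein_prob:
                words.append(_protein_name(rng))
                pos_tags.append("NN")
                is_protein[i] = True
            else:
                words.append(rng.choice(vocab))
                pos_tags.append(_weighted_choice(rng, _BACKGROUND_POS))
        else:
            word = rng.choice(vocab)
            if rng.random() < config.signal_strength:
                word = _plant_signature(rng, word, SIGNATURES[label])
            words.append(word)
            pos_tags.append(_weighted_choice(rng, _TRIGGER_POS))
    # weak sentence-level cue: overwrite one negative, non-protein slot
    trigger_classes = sorted({l for l in labels if l != NEGATIVE_LABEL})
    if trigger_classes and rng.random() < config.context_word_prob:
        slots = [
            i
            for i in range(n)
            if labels[i] == NEGATIVE_LABEL and not is_protein[i]
        ]
        if slots:
            slot = rng.choice(slots)
            words[slot] = CONTEXT_WORDS[rng.choice(trigger_classes)]
    text = " ".join(words)
    tokens: list[Token] = []
    cursor = 0
    for i, word in enumerate(words):
        tokens.append(
            Token(
                index=i,
                text=word,
                pos=pos_tags[i],
                char_start=cursor,
                char_end=cursor + len(word),
            )
        )
        cursor += len(word) + 1
    edges = [
        DependencyEdge(governor=g, dependent=d, relation=rng.choice(_RELATIONS))
        for g, d in _projective_edges(rng, n)
    ]
    entities: list[Entity] = []
    for i in range(n):
        if is_protein[i]:
            entities.append(
                Entity(id=f"{sent_id}.e{len(entities)}", type="Protein", head=i, given=True)
            )
    trigger_entities: list[Entity] = []
    for i, label in enumerate(labels):
        if label != NEGATIVE_LABEL:
            ent = Entity(
                id=f"{sent_id}.e{len(entities)}", type=label, head=i, given=False
            )
            entities.append(ent)
            trigger_entities.append(ent)
    interactions: list[Interaction] = []
    proteins = [e for e in entities if e.type == "Protein"]
    for ent in trigger_entities:
        targets = [e for e in entities if e.id != ent.id]
        if proteins:
            theme = rng.choice(proteins)
            interactions.append(
                Interaction(
                    id=f"{sent_id}.i{len(interactions)}",
                    from_entity=ent.id,
                    to_entity=theme.id,
                    type="Theme",
                )
            )
        if ent.type.endswith("egulation") and targets and rng.random() < 0.5:
            cause = rng.choice(targets)
            if not any(
                x.from_entity == ent.id and x.to_entity == cause.id
                for x in interactions
            ):
                interactions.append(
                    Interaction(
                        id=f"{sent_id}.i{len(interactions)}",
                        from_entity=ent.id,
                        to_entity=cause.id,
                        type="Cause",
                    )
                )
    return SentenceGraph(
        id=sent_id,
        text=text,
        tokens=tokens,
        edges=edges,
        entities=entities,
        interactions=interactions,
    )


def generate(config: SynthConfig | None = None, seed: int | None = None) -> Corpus:
    """Generate a corpus fully determined by the configuration and seed."""
    config = config or SynthConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = random.Random(config.seed)
    vocab = _make_vocab(rng, config.vocab_size)
    corpus = Corpus(id=f"synth-{config.seed}")
    for d in range(config.n_documents):
        doc = Document(id=f"d{d}")
        n_sent = rng.randint(*config.sentences_per_doc)
        for s in range(n_sent):
            doc.sentences.append(
                _generate_sentence(rng, f"d{d}.s{s}", vocab, config)
            )
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def split(
    corpus: Corpus,
    fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[Corpus, ...]:
    """Document-level disjoint split (train/devel/test roles), deterministic.

    Documents are shuffled by the seed and allocated to the splits by the
    given fractions, remainders going to the earliest splits.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    docs = list(corpus.documents)
    if not docs:
        raise ValueError("cannot split an empty corpus")
    rng = random.Random(seed)
    order = list(range(len(docs)))
    rng.shuffle(order)
    counts = [int(f * len(docs)) for f in fractions]
    leftover = len(docs) - sum(counts)
    for i in range(leftover):
        counts[i % len(counts)] += 1
    parts: list[Corpus] = []
    start = 0
    for part_index, count in enumerate(counts):
        chosen = sorted(order[start : start + count])
        start += count
        parts.append(
            Corpus(
                id=f"{corpus.id}-part{part_index}",
                documents=[docs[i] for i in chosen],
            )
        )
    return tuple(parts)
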
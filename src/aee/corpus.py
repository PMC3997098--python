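"""Stand-off annotated corpus model and XML I/O.

A :class:`Corpus` holds documents, each a list of sentences.  Every sentence
is a :class:`SentenceGraph`: word tokens with part-of-speech tags and
character offsets, directed syntactic dependency edges (governor ->
dependent), entity annotations (given proteins and event triggers) anchored
to head tokens, and Theme/Cause interactions between entities.  The directed
dependency graph must be acyclic; path queries use the undirected view.

The XML dialect is a documented stand-in for interaction-XML style formats::

    <corpus id="c">
      <document id="d0">
        <sentence id="d0.s0" text="IL-4 involves NFAT1">
          <token id="t0" text="IL-4" POS="NN" charOffset="0-4"/>
          <dependency t1="t1" t2="t0" type="nsubj"/>
          <entity id="e0" type="Protein" headOffset="0-4" given="True"/>
          <interaction id="i0" e1="e1" e2="e0" type="Theme"/>
        </sentence>
      </document>
    </corpus>

Character offsets are 0-based half-open.  ``t1`` is the governor and ``t2``
the dependent of a dependency.  ``headOffset`` must equal the ``charOffset``
of exactly one token.  Unknown attributes are preserved and round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from lxml import etree

EVENT_TYPES: tuple[str, ...] = (
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Localization",
    "Binding",
    "Phosphorylation",
    "Regulation",
    "Positive_regulation",
    "Negative_regulation",
)
ENTITY_TYPES: frozenset[str] = frozenset(("Protein",) + EVENT_TYPES)
INTERACTION_TYPES: frozenset[str] = frozenset({"Theme", "Cause"})

#: label used for tokens/pairs that are not triggers/relations
NEGATIVE_LABEL = "neg"


class CorpusError(Exception):
    """Base class for corpus I/O and validation failures."""


class CorpusParseError(CorpusError):
    """Malformed XML; the message names the offending line when known."""


class CorpusValidationError(CorpusError):
    """Structurally well-formed input violating a corpus invariant."""


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    pos: str
    char_start: int
    char_end: int
    extra: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class DependencyEdge:
    governor: int
    dependent: int
    relation: str
    extra: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class Entity:
    id: str
    type: str
    head: int
    given: bool = False
    extra: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class Interaction:
    id: str
    from_entity: str
    to_entity: str
    type: str
    extra: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class PathStep:
    """One traversal step of a dependency path.

    ``forward`` is True when the step follows the edge's stored orientation
    (governor to dependent), False when it runs against it.
    """

    edge: DependencyEdge
    forward: bool

    @property
    def direction(self) -> str:
        return "gov>dep" if self.forward else "dep>gov"


@dataclass(frozen=True)
class DependencyPath:
    """A shortest dependency path: visited token indices and traversal steps."""

    token_indices: tuple[int, ...]
    steps: tuple[PathStep, ...]

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class SentenceGraph:
    id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    edges: list[DependencyEdge] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    extra: tuple[tuple[str, str], ...] = ()

    def entity_by_id(self, entity_id: str) -> Entity:
        for entity in self.entities:
            if entity.id == entity_id:
                return entity
        raise KeyError(entity_id)

    def validate(self) -> None:
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise CorpusValidationError(
                    f"sentence {self.id}: token indices not contiguous at {tok.index}"
                )
            if not (0 <= tok.char_start < tok.char_end <= len(self.text)):
                raise CorpusValidationError(
                    f"sentence {self.id}: token {i} offsets "
                    f"{tok.char_start}-{tok.char_end} outside sentence text"
                )
        for edge in self.edges:
            if edge.governor == edge.dependent:
                raise CorpusValidationError(
                    f"sentence {self.id}: self-loop dependency on token {edge.governor}"
                )
            for idx in (edge.governor, edge.dependent):
                if not 0 <= idx < n:
                    raise CorpusValidationError(
                        f"sentence {self.id}: dependency references token {idx} "
                        f"but sentence has {n} tokens"
                    )
        digraph = nx.DiGraph()
        digraph.add_nodes_from(range(n))
        digraph.add_edges_from((e.governor, e.dependent) for e in self.edges)
        if not nx.is_directed_acyclic_graph(digraph):
            raise CorpusValidationError(
                f"sentence {self.id}: dependency graph contains a directed cycle"
            )
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise CorpusValidationError(f"sentence {self.id}: duplicate entity ids")
        for entity in self.entities:
            if entity.type not in ENTITY_TYPES:
                raise CorpusValidationError(
                    f"sentence {self.id}: unknown entity type {entity.type!r}"
                )
            if not 0 <= entity.head < n:
                raise CorpusValidationError(
                    f"sentence {self.id}: entity {entity.id} head token "
                    f"{entity.head} out of range"
                )
        known = set(ids)
        for inter in self.interactions:
            if inter.type not in INTERACTION_TYPES:
                raise CorpusValidationError(
                    f"sentence {self.id}: unknown interaction type {inter.type!r}"
                )
            for ref in (inter.from_entity, inter.to_entity):
                if ref not in known:
                    raise CorpusValidationError(
                        f"sentence {self.id}: interaction {inter.id} references "
                        f"missing entity {ref!r}"
                    )


@dataclass
class Document:
    id: str
    sentences: list[SentenceGraph] = field(default_factory=list)
    extra: tuple[tuple[str, str], ...] = ()


@dataclass
class Corpus:
    id: str = "corpus"
    documents: list[Document] = field(default_factory=list)
    extra: tuple[tuple[str, str], ...] = ()

    def sentences(self):
        for doc in self.documents:
            yield from doc.sentences

    def validate(self) -> None:
        doc_ids = [d.id for d in self.documents]
        if len(doc_ids) != len(set(doc_ids)):
            raise CorpusValidationError("duplicate document ids")
        sent_ids = [s.id for s in self.sentences()]
        if len(sent_ids) != len(set(sent_ids)):
            raise CorpusValidationError("duplicate sentence ids")
        for sentence in self.sentences():
            sentence.validate()


# ---------------------------------------------------------------------------
# parsing


def _extra_attrs(elem, known: tuple[str, ...]) -> tuple[tuple[str, str], ...]:
    return tuple(sorted((k, v) for k, v in elem.attrib.items() if k not in known))


def _offset(value: str, elem) -> tuple[int, int]:
    try:
        start, _, end = value.partition("-")
        return int(start), int(end)
    except ValueError:
        raise CorpusParseError(
            f"line {elem.sourceline}: bad charOffset {value!r}"
        ) from None


def _parse_sentence(elem) -> SentenceGraph:
    sent = SentenceGraph(
        id=elem.get("id", ""),
        text=elem.get("text", ""),
        extra=_extra_attrs(elem, ("id", "text")),
    )
    offset_to_index: dict[tuple[int, int], int] = {}
    token_ids: dict[str, int] = {}
    for child in elem:
        tag = child.tag
        if tag == "token":
            start, end = _offset(child.get("charOffset", ""), child)
            index = len(sent.tokens)
            token_ids[child.get("id", f"t{index}")] = index
            offset_to_index[(start, end)] = index
            sent.tokens.append(
                Token(
                    index=index,
                    text=child.get("text", ""),
                    pos=child.get("POS", ""),
                    char_start=start,
                    char_end=end,
                    extra=_extra_attrs(child, ("id", "text", "POS", "charOffset")),
                )
            )
        elif tag == "dependency":
            for key in ("t1", "t2"):
                if child.get(key) not in token_ids:
                    raise CorpusValidationError(
                        f"line {child.sourceline}: dependency references "
                        f"unknown token {child.get(key)!r}"
                    )
            sent.edges.append(
                DependencyEdge(
                    governor=token_ids[child.get("t1")],
                    dependent=token_ids[child.get("t2")],
                    relation=child.get("type", ""),
                    extra=_extra_attrs(child, ("t1", "t2", "type")),
                )
            )
        elif tag == "entity":
            head_offset = _offset(child.get("headOffset", ""), child)
            if head_offset not in offset_to_index:
                raise CorpusValidationError(
                    f"line {child.sourceline}: entity headOffset "
                    f"{child.get('headOffset')!r} matches no token"
                )
            sent.entities.append(
                Entity(
                    id=child.get("id", ""),
                    type=child.get("type", ""),
                    head=offset_to_index[head_offset],
                    given=child.get("given", "False") == "True",
                    extra=_extra_attrs(child, ("id", "type", "headOffset", "given")),
                )
            )
        elif tag == "interaction":
            sent.interactions.append(
                Interaction(
                    id=child.get("id", ""),
                    from_entity=child.get("e1", ""),
                    to_entity=child.get("e2", ""),
                    type=child.get("type", ""),
                    extra=_extra_attrs(child, ("id", "e1", "e2", "type")),
                )
            )
        else:
            raise CorpusParseError(
                f"line {child.sourceline}: unexpected element <{tag}>"
            )
    return sent


def parse_corpus(xml_text: str | bytes) -> Corpus:
    """Parse the stand-off XML dialect into a validated :class:`Corpus`."""
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML: {exc}") from exc
    if root.tag != "corpus":
        raise CorpusParseError(f"expected <corpus> root, got <{root.tag}>")
    corpus = Corpus(id=root.get("id", "corpus"), extra=_extra_attrs(root, ("id",)))
    for doc_elem in root:
        if doc_elem.tag != "document":
            raise CorpusParseError(
                f"line {doc_elem.sourceline}: expected <document>, got <{doc_elem.tag}>"
            )
        doc = Document(id=doc_elem.get("id", ""), extra=_extra_attrs(doc_elem, ("id",)))
        for sent_elem in doc_elem:
            if sent_elem.tag != "sentence":
                raise CorpusParseError(
                    f"line {sent_elem.sourceline}: expected <sentence>, "
                    f"got <{sent_elem.tag}>"
                )
            doc.sentences.append(_parse_sentence(sent_elem))
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# writing


def _set_extra(elem, extra: tuple[tuple[str, str], ...]) -> None:
    for key, value in extra:
        elem.set(key, value)


def write_corpus(corpus: Corpus) -> str:
    """Serialise a corpus deterministically (stable element/attribute order)."""
    corpus.validate()
    root = etree.Element("corpus", id=corpus.id)
    _set_extra(root, corpus.extra)
    for doc in corpus.documents:
        doc_elem = etree.SubElement(root, "document", id=doc.id)
        _set_extra(doc_elem, doc.extra)
        for sent in doc.sentences:
            sent_elem = etree.SubElement(doc_elem, "sentence", id=sent.id, text=sent.text)
            _set_extra(sent_elem, sent.extra)
            for tok in sent.tokens:
                tok_elem = etree.SubElement(
                    sent_elem,
                    "token",
                    id=f"t{tok.index}",
                    text=tok.text,
                    POS=tok.pos,
                    charOffset=f"{tok.char_start}-{tok.char_end}",
                )
                _set_extra(tok_elem, tok.extra)
            for edge in sent.edges:
                dep_elem = etree.SubElement(
                    sent_elem,
                    "dependency",
                    t1=f"t{edge.governor}",
                    t2=f"t{edge.dependent}",
                    type=edge.relation,
                )
                _set_extra(dep_elem, edge.extra)
            for entity in sent.entities:
                head = sent.tokens[entity.head]
                ent_elem = etree.SubElement(
                    sent_elem,
                    "entity",
                    id=entity.id,
                    type=entity.type,
                    headOffset=f"{head.char_start}-{head.char_end}",
                    given=str(entity.given),
                )
                _set_extra(ent_elem, entity.extra)
            for inter in sent.interactions:
                int_elem = etree.SubElement(
                    sent_elem,
                    "interaction",
                    id=inter.id,
                    e1=inter.from_entity,
                    e2=inter.to_entity,
                    type=inter.type,
                )
                _set_extra(int_elem, inter.extra)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# shortest dependency path


def _adjacency(graph: SentenceGraph) -> dict[int, dict[int, DependencyEdge]]:
    """Undirected adjacency; parallel edges resolved by smallest (relation, gov)."""
    adj: dict[int, dict[int, DependencyEdge]] = {t.index: {} for t in graph.tokens}
    for edge in graph.edges:
        for a, b in ((edge.governor, edge.dependent), (edge.dependent, edge.governor)):
            current = adj[a].get(b)
            if current is None or (edge.relation, edge.governor) < (
                current.relation,
                current.governor,
            ):
                adj[a][b] = edge
    return adj


def shortest_dependency_path(
    graph: SentenceGraph, a: int, b: int
) -> DependencyPath | None:
    """Shortest path between tokens ``a`` and ``b`` in the undirected view.

    Among equal-length paths the one with the lexicographically smallest
    token-index sequence is returned.  Returns ``None`` when the tokens are
    disconnected.  ``a == b`` gives the empty path.
    """
    n = len(graph.tokens)
    for idx in (a, b):
        if not 0 <= idx < n:
            raise IndexError(f"token index {idx} out of range for {n} tokens")
    if a == b:
        return DependencyPath(token_indices=(a,), steps=())
    adj = _adjacency(graph)
    # BFS from b gives distance-to-target; greedy descent from a over
    # neighbours in increasing index order yields the lexicographically
    # smallest shortest token sequence.
    dist = {b: 0}
    frontier = [b]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    nxt.append(nb)
        frontier = nxt
    if a not in dist:
        return None
    tokens = [a]
    steps: list[PathStep] = []
    current = a
    while current != b:
        nxt = min(
            nb for nb in adj[current] if dist.get(nb, -1) == dist[current] - 1
        )
        edge = adj[current][nxt]
        steps.append(PathStep(edge=edge, forward=edge.governor == current))
        tokens.append(nxt)
        current = nxt
    return DependencyPath(token_indices=tuple(tokens), steps=tuple(steps))
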
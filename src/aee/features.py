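"""Feature generation for trigger and edge detection.

Trigger features (per target token) come in six classes:

1. sentence feature — bag of words over the whole sentence;
2. main feature — POS tag, Porter stem, and the removed suffix (nonstem);
3. linear order feature — text/POS of neighbours in surface order;
4. content feature — micro-lexical: capitalisation flags, digit/hyphen
   flags, and lowercased character 2-grams (``dt``) and 3-grams (``tt``);
   the ``prime`` variant (4') adds character 4-grams (``ft``);
5. attached edge feature — labels/direction/neighbour of dependency edges
   incident to the target token;
6. chain feature — walks of bounded depth through the dependency graph
   from the target token; the ``prime`` variant (6') merges the class-5
   and class-6 strings into one namespace with duplicates collapsed.

Edge features (per ordered entity pair) use classes 1, 2, 4, 5, 6, 7, 8
(the terminus-token class 3 is absorbed into the entity class 1):
entity, path length (2' adds a binned length), single element, path grams,
path edge, sentence (7' adds a POS bag of words), and GENIA flags from
given-protein annotations on the path.

Every feature is a namespaced string ``class<id>:<rule>=<value>`` mapped to
a count; multisets are plain :class:`collections.Counter` objects, so class
subsets and merges are ordinary multiset operations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .corpus import (
    Entity,
    SentenceGraph,
    shortest_dependency_path,
)
from .stem import nonstem, stem

FeatureMultiset = Counter

TRIGGER_CLASS_IDS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
EDGE_CLASS_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 8)
#: classes for which a modified (prime) variant is defined
PRIME_VARIANTS: frozenset[tuple[str, int]] = frozenset(
    {("trigger", 4), ("trigger", 6), ("edge", 2), ("edge", 7)}
)

TRIGGER_CLASS_NAMES: dict[int, str] = {
    1: "sentence feature",
    2: "main feature",
    3: "linear order feature",
    4: "content feature",
    5: "attached edge feature",
    6: "chain feature",
}
EDGE_CLASS_NAMES: dict[int, str] = {
    1: "entity feature",
    2: "path length feature",
    4: "single element feature",
    5: "path grams feature",
    6: "path edge feature",
    7: "sentence feature",
    8: "GENIA feature",
}


class ConfigurationError(ValueError):
    """Invalid feature-generation configuration."""


@dataclass(frozen=True, order=True)
class FeatureClassId:
    """A feature class: detection phase, numeric id, base or prime variant."""

    phase: str
    id: int
    variant: str = "base"

    def __post_init__(self) -> None:
        if self.phase not in ("trigger", "edge"):
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        valid = TRIGGER_CLASS_IDS if self.phase == "trigger" else EDGE_CLASS_IDS
        if self.id not in valid:
            raise ConfigurationError(
                f"unknown {self.phase} feature class id {self.id}"
            )
        if self.variant not in ("base", "prime"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.variant == "prime" and (self.phase, self.id) not in PRIME_VARIANTS:
            raise ConfigurationError(
                f"no prime variant defined for {self.phase} class {self.id}"
            )

    @classmethod
    def parse(cls, phase: str, spec: str | int) -> "FeatureClassId":
        """Parse "4" or "4p"/"4'" into a FeatureClassId."""
        text = str(spec).strip()
        variant = "base"
        if text.endswith(("p", "'", "′")):
            variant = "prime"
            text = text[:-1]
        return cls(phase=phase, id=int(text), variant=variant)

    def __str__(self) -> str:
        return f"{self.id}'" if self.variant == "prime" else str(self.id)


def _feat(class_id: int, rule: str, value: str) -> str:
    return f"class{class_id}:{rule}={value}"


def _char_ngrams(text: str, n: int) -> list[str]:
    lowered = text.lower()
    return [lowered[i : i + n] for i in range(len(lowered) - n + 1)]


# ---------------------------------------------------------------------------
# trigger feature classes


def sentence_features(graph: SentenceGraph) -> FeatureMultiset:
    """Class 1: sentence bag of words (lowercased), counted."""
    return Counter(_feat(1, "bow", tok.text.lower()) for tok in graph.tokens)


def main_features(graph: SentenceGraph, t: int) -> FeatureMultiset:
    """Class 2: POS tag, Porter stem, and the suffix removed by stemming."""
    tok = graph.tokens[t]
    feats = Counter(
        {_feat(2, "pos", tok.pos): 1, _feat(2, "stem", stem(tok.text)): 1}
    )
    suffix = nonstem(tok.text)
    if suffix:
        feats[_feat(2, "nonstem", suffix)] = 1
    return feats


def linear_order_features(
    graph: SentenceGraph, t: int, window: int = 3
) -> FeatureMultiset:
    """Class 3: text and POS of surface-order neighbours within ±window."""
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    feats: FeatureMultiset = Counter()
    for offset in range(-window, window + 1):
        if offset == 0:
            continue
        j = t + offset
        if 0 <= j < len(graph.tokens):
            nb = graph.tokens[j]
            feats[_feat(3, f"lin_{offset:+d}_text", nb.text.lower())] += 1
            feats[_feat(3, f"lin_{offset:+d}_pos", nb.pos)] += 1
    return feats


def content_features(
    graph: SentenceGraph, t: int, variant: str = "base"
) -> FeatureMultiset:
    """Class 4 (4' with ``variant="prime"``): micro-lexical token features.

    ``upper`` flags capitalisation, ``has`` flags digits/hyphens, ``dt``,
    ``tt`` and (prime only) ``ft`` are lowercased character 2/3/4-grams.
    """
    text = graph.tokens[t].text
    feats: FeatureMultiset = Counter()
    if text[:1].isupper():
        feats[_feat(4, "upper", "initial")] += 1
    if text.isupper() and any(c.isalpha() for c in text):
        feats[_feat(4, "upper", "all")] += 1
    if any(c.isdigit() for c in text):
        feats[_feat(4, "has", "digit")] += 1
    if "-" in text:
        feats[_feat(4, "has", "hyphen")] += 1
    for rule, n in (("dt", 2), ("tt", 3)) + ((("ft", 4),) if variant == "prime" else ()):
        for gram in _char_ngrams(text, n):
            feats[_feat(4, rule, gram)] += 1
    return feats


def attached_edge_features(graph: SentenceGraph, t: int) -> FeatureMultiset:
    """Class 5: relation, direction, and neighbour text/POS per incident edge."""
    feats: FeatureMultiset = Counter()
    for edge in graph.edges:
        if edge.governor == t or edge.dependent == t:
            is_gov = edge.governor == t
            nb = graph.tokens[edge.dependent if is_gov else edge.governor]
            feats[_feat(5, "rel", edge.relation)] += 1
            feats[_feat(5, "dir", "gov" if is_gov else "dep")] += 1
            feats[_feat(5, "nbr_text", nb.text.lower())] += 1
            feats[_feat(5, "nbr_pos", nb.pos)] += 1
    return feats


def _walks(
    adj: dict[int, list[tuple[int, str, bool]]], start: int, depth: int
) -> list[tuple[tuple[str, ...], int]]:
    """Simple directed walks (no revisits) of length 1..depth from start.

    Each step contributes its relation label tagged with the traversal
    direction (">" with, "<" against edge orientation).  Returns (label
    sequence, terminal token) pairs.
    """
    out: list[tuple[tuple[str, ...], int]] = []

    def extend(node: int, labels: tuple[str, ...], seen: frozenset[int]) -> None:
        if len(labels) >= depth:
            return
        for nb, rel, forward in adj[node]:
            if nb in seen:
                continue
            step = (">" if forward else "<") + rel
            out.append((labels + (step,), nb))
            extend(nb, labels + (step,), seen | {nb})

    extend(start, (), frozenset({start}))
    return out


def _walk_adjacency(
    graph: SentenceGraph,
) -> dict[int, list[tuple[int, str, bool]]]:
    adj: dict[int, list[tuple[int, str, bool]]] = {
        tok.index: [] for tok in graph.tokens
    }
    for edge in graph.edges:
        adj[edge.governor].append((edge.dependent, edge.relation, True))
        adj[edge.dependent].append((edge.governor, edge.relation, False))
    for lst in adj.values():
        lst.sort()
    return adj


def chain_features(
    graph: SentenceGraph, t: int, depth: int = 3, variant: str = "base"
) -> FeatureMultiset:
    """Class 6 (6' with ``variant="prime"``): dependency-walk features.

    One feature per walk of length 1..depth from the target token:
    direction-tagged relation labels joined with ``.`` plus the terminal
    token text.  The prime variant merges the class-5 and class-6 feature
    strings into the class-6 namespace with duplicates collapsed to
    count 1 — the dependency-feature merge.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    adj = _walk_adjacency(graph)
    feats: FeatureMultiset = Counter()
    for labels, terminal in _walks(adj, t, depth):
        term = graph.tokens[terminal].text.lower()
        feats[_feat(6, "chain", ".".join(labels) + ":" + term)] += 1
    if variant == "prime":
        merged = {key.split(":", 1)[1] for key in feats}
        merged |= {
            key.split(":", 1)[1] for key in attached_edge_features(graph, t)
        }
        return Counter({_feat(6, "merged", key): 1 for key in sorted(merged)})
    return feats


_TRIGGER_GENERATORS = {1, 2, 3, 4, 5, 6}


def trigger_features(
    graph: SentenceGraph,
    t: int,
    classes: list[FeatureClassId],
    window: int = 3,
    depth: int = 3,
) -> FeatureMultiset:
    """Union of the requested trigger feature classes for token ``t``."""
    feats: FeatureMultiset = Counter()
    for cid in classes:
        if cid.phase != "trigger":
            raise ConfigurationError(f"{cid} is not a trigger class")
        if cid.id == 1:
            feats += sentence_features(graph)
        elif cid.id == 2:
            feats += main_features(graph, t)
        elif cid.id == 3:
            feats += linear_order_features(graph, t, window=window)
        elif cid.id == 4:
            feats += content_features(graph, t, variant=cid.variant)
        elif cid.id == 5:
            feats += attached_edge_features(graph, t)
        elif cid.id == 6:
            feats += chain_features(graph, t, depth=depth, variant=cid.variant)
    return feats


# ---------------------------------------------------------------------------
# edge feature classes

_LENGTH_BINS = ("1", "2", "3", "4", "5+")


def _binned_length(length: int) -> str:
    return _LENGTH_BINS[min(max(length, 1), 5) - 1]


def edge_features(
    graph: SentenceGraph,
    e1: Entity,
    e2: Entity,
    classes: list[FeatureClassId],
) -> FeatureMultiset:
    """Union of the requested edge feature classes for the pair (e1, e2).

    When the head tokens are disconnected in the dependency graph, only the
    non-path classes (entity, sentence, and the pair's given flags) are
    emitted.
    """
    feats: FeatureMultiset = Counter()
    path = shortest_dependency_path(graph, e1.head, e2.head)
    labels = (
        [(">" if s.forward else "<") + s.edge.relation for s in path.steps]
        if path is not None
        else []
    )
    for cid in classes:
        if cid.phase != "edge":
            raise ConfigurationError(f"{cid} is not an edge class")
        if cid.id == 1:
            for role, ent in (("e1", e1), ("e2", e2)):
                head = graph.tokens[ent.head]
                feats[_feat(1, f"{role}_type", ent.type)] += 1
                feats[_feat(1, f"{role}_text", head.text.lower())] += 1
                feats[_feat(1, f"{role}_pos", head.pos)] += 1
        elif cid.id == 2:
            if path is not None:
                feats[_feat(2, "pathlen", str(len(path)))] += 1
                if cid.variant == "prime" and len(path) > 0:
                    feats[_feat(2, "pathbin", _binned_length(len(path)))] += 1
        elif cid.id == 4:
            if path is not None:
                for idx in path.token_indices:
                    feats[_feat(4, "tok", graph.tokens[idx].text.lower())] += 1
                for step in path.steps:
                    feats[_feat(4, "dep", step.edge.relation)] += 1
        elif cid.id == 5:
            for n in (2, 3, 4):
                for i in range(len(labels) - n + 1):
                    feats[_feat(5, f"gram{n}", ".".join(labels[i : i + n]))] += 1
        elif cid.id == 6:
            for label in labels:
                feats[_feat(6, "edge", label)] += 1
        elif cid.id == 7:
            for tok in graph.tokens:
                feats[_feat(7, "bow", tok.text.lower())] += 1
                if cid.variant == "prime":
                    feats[_feat(7, "posbow", tok.pos)] += 1
        elif cid.id == 8:
            on_path = set(path.token_indices) if path is not None else set()
            for ent in graph.entities:
                if ent.given and ent.head in on_path:
                    feats[_feat(8, "given_on_path", ent.type)] += 1
            feats[_feat(8, "e1_given", str(e1.given))] += 1
            feats[_feat(8, "e2_given", str(e2.given))] += 1
    return feats


def feature_size(multisets: list[FeatureMultiset]) -> int:
    """Number of distinct feature types across instances (Table-style size)."""
    distinct: set[str] = set()
    for ms in multisets:
        distinct.update(ms)
    return len(distinct)
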
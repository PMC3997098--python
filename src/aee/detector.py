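"""Trigger and edge detection as multiclass classification, plus evaluation.

Trigger detection labels every token with one of the nine biomedical event
classes or the negative class (10-way classification).  Edge detection
labels ordered (trigger entity, entity) pairs as Theme, Cause, or negative.

The learner behind :func:`train` is a pluggable contract — anything with
``fit(multisets, labels)`` and ``scores(multisets) -> list of {label:
score}`` works.  The shipped implementation is a one-vs-rest logistic
regression over hashed-to-sparse feature multisets; its class-probability
scores are positive, which makes the precision-recall trade-off below
monotone.

The trade-off: at prediction time the negative-class score is multiplied by
``beta`` before the argmax, so ``beta < 1`` pushes tokens toward trigger
classes (raising recall at the cost of precision).  It applies to the
trigger phase only; edge prediction is a plain argmax.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import (
    EVENT_TYPES,
    INTERACTION_TYPES,
    NEGATIVE_LABEL,
    Corpus,
    SentenceGraph,
)
from .features import (
    FeatureClassId,
    FeatureMultiset,
    edge_features,
    trigger_features,
)

TRIGGER_LABELS: tuple[str, ...] = EVENT_TYPES + (NEGATIVE_LABEL,)
EDGE_LABELS: tuple[str, ...] = tuple(sorted(INTERACTION_TYPES)) + (NEGATIVE_LABEL,)


class DetectorError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectorConfig:
    """Detector parameters.

    ``C`` is the regularisation constant of the linear learner (larger =
    weaker regularisation), ``beta`` the negative-class score multiplier
    used in trigger prediction, ``classes`` the feature-class subset,
    ``window``/``depth`` the linear-order window and chain depth.
    """

    classes: tuple[FeatureClassId, ...]
    C: float = 1.0
    beta: float = 0.6
    window: int = 3
    depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @classmethod
    def for_phase(cls, phase: str, class_specs: Iterable[str | int], **kw):
        classes = tuple(FeatureClassId.parse(phase, s) for s in class_specs)
        return cls(classes=classes, **kw)


@dataclass(frozen=True)
class Instance:
    id: str
    features: FeatureMultiset
    gold: str


def trigger_instances(
    corpus: Corpus,
    classes: Sequence[FeatureClassId],
    window: int = 3,
    depth: int = 3,
) -> list[Instance]:
    """One instance per token; gold label from non-given entity heads."""
    out: list[Instance] = []
    for sent in corpus.sentences():
        head_label: dict[int, str] = {}
        for ent in sent.entities:
            if not ent.given and ent.type in EVENT_TYPES:
                head_label.setdefault(ent.head, ent.type)
        for tok in sent.tokens:
            feats = trigger_features(
                sent, tok.index, list(classes), window=window, depth=depth
            )
            out.append(
                Instance(
                    id=f"{sent.id}.t{tok.index}",
                    features=feats,
                    gold=head_label.get(tok.index, NEGATIVE_LABEL),
                )
            )
    return out


def edge_candidates(sent: SentenceGraph) -> list[tuple]:
    """Ordered (event entity, any other entity) pairs in one sentence."""
    events = [e for e in sent.entities if e.type in EVENT_TYPES]
    pairs = []
    for src in events:
        for dst in sent.entities:
            if dst.id != src.id:
                pairs.append((src, dst))
    return pairs


def edge_instances(
    corpus: Corpus, classes: Sequence[FeatureClassId]
) -> list[Instance]:
    """One instance per candidate entity pair; gold label from interactions."""
    out: list[Instance] = []
    for sent in corpus.sentences():
        gold = {
            (i.from_entity, i.to_entity): i.type for i in sent.interactions
        }
        for src, dst in edge_candidates(sent):
            feats = edge_features(sent, src, dst, list(classes))
            out.append(
                Instance(
                    id=f"{sent.id}.{src.id}>{dst.id}",
                    features=feats,
                    gold=gold.get((src.id, dst.id), NEGATIVE_LABEL),
                )
            )
    return out


# ---------------------------------------------------------------------------
# learner contract and shipped implementation


class LinearScorer(Protocol):
    def fit(self, multisets: Sequence[Mapping[str, int]], labels: Sequence[str]):
        ...

    def scores(self, multisets: Sequence[Mapping[str, int]]) -> list[dict[str, float]]:
        ...


class LogisticScorer:
    """One-vs-rest logistic regression over sparse feature counts.

    Emits class probabilities as scores (all positive), deterministic for a
    fixed seed and insensitive to training-instance order.
    """

    def __init__(self, C: float = 1.0, seed: int = 0, max_iter: int = 200):
        self.C = C
        self.seed = seed
        self.max_iter = max_iter
        self._vec: DictVectorizer | None = None
        self._clf: LogisticRegression | None = None

    def fit(self, multisets, labels):
        if not multisets:
            raise DetectorError("no training instances")
        if all(len(m) == 0 for m in multisets):
            raise DetectorError("empty feature set: no features generated")
        self._vec = DictVectorizer(sparse=True)
        X = self._vec.fit_transform([dict(m) for m in multisets])
        self._clf = LogisticRegression(
            C=self.C,
            max_iter=self.max_iter,
            random_state=self.seed,
            solver="lbfgs",
        )
        self._clf.fit(X, list(labels))
        return self

    def fit_matrix(self, X: sp.spmatrix, labels) -> "LogisticScorer":
        """Fit directly on a pre-vectorised design matrix (fast path)."""
        if X.shape[1] == 0:
            raise DetectorError("empty feature set: design matrix has no columns")
        self._clf = LogisticRegression(
            C=self.C,
            max_iter=self.max_iter,
            random_state=self.seed,
            solver="lbfgs",
        )
        self._clf.fit(X, list(labels))
        return self

    def _proba(self, X) -> list[dict[str, float]]:
        proba = self._clf.predict_proba(X)
        labels = self._clf.classes_
        return [dict(zip(labels, row)) for row in proba]

    def scores(self, multisets):
        if self._vec is None or self._clf is None:
            raise DetectorError("scorer is not fitted")
        X = self._vec.transform([dict(m) for m in multisets])
        return self._proba(X)

    def scores_matrix(self, X: sp.spmatrix) -> list[dict[str, float]]:
        if self._clf is None:
            raise DetectorError("scorer is not fitted")
        return self._proba(X)


@dataclass
class Model:
    """A trained detector: maps feature multisets to per-class scores."""

    phase: str
    config: DetectorConfig
    scorer: LinearScorer
    labels: tuple[str, ...]

    def class_scores(
        self, multisets: Sequence[Mapping[str, int]]
    ) -> list[dict[str, float]]:
        """Scores with every label of the phase present (0 when unseen)."""
        raw = self.scorer.scores(multisets)
        return [
            {label: row.get(label, 0.0) for label in self.labels} for row in raw
        ]


def train(
    corpus: Corpus,
    phase: str,
    config: DetectorConfig,
    scorer: LinearScorer | None = None,
) -> Model:
    """Train a detector for ``phase`` ("trigger" or "edge") on a gold corpus."""
    labels = TRIGGER_LABELS if phase == "trigger" else EDGE_LABELS
    if phase == "trigger":
        instances = trigger_instances(
            corpus, config.classes, window=config.window, depth=config.depth
        )
    elif phase == "edge":
        instances = edge_instances(corpus, config.classes)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    unseen = {inst.gold for inst in instances} - set(labels)
    if unseen:
        raise DetectorError(f"corpus contains labels outside the phase: {unseen}")
    if scorer is None:
        scorer = LogisticScorer(C=config.C, seed=config.seed)
    scorer.fit([inst.features for inst in instances], [inst.gold for inst in instances])
    return Model(phase=phase, config=config, scorer=scorer, labels=labels)


def argmax_with_beta(
    score_rows: Sequence[Mapping[str, float]],
    labels: Sequence[str],
    beta: float = 1.0,
) -> list[str]:
    """Argmax with the negative-class score multiplied by beta.

    Ties break by fixed label order with the negative class last.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    ordered = [l for l in labels if l != NEGATIVE_LABEL] + [NEGATIVE_LABEL]
    out = []
    for row in score_rows:
        best_label = None
        best_score = -np.inf
        for label in ordered:
            score = row.get(label, 0.0)
            if label == NEGATIVE_LABEL:
                score *= beta
            if score > best_score:
                best_score = score
                best_label = label
        out.append(best_label)
    return out


def predict_triggers(
    model: Model, corpus: Corpus, beta: float | None = None
) -> dict[str, str]:
    """Per-token predicted labels with the beta trade-off applied."""
    beta = model.config.beta if beta is None else beta
    instances = trigger_instances(
        corpus, model.config.classes, window=model.config.window, depth=model.config.depth
    )
    rows = model.class_scores([inst.features for inst in instances])
    predicted = argmax_with_beta(rows, model.labels, beta=beta)
    return dict(zip((inst.id for inst in instances), predicted))


def predict_edges(model: Model, corpus: Corpus) -> dict[str, str]:
    """Per-candidate-pair predicted labels (plain argmax, no beta)."""
    instances = edge_instances(corpus, model.config.classes)
    rows = model.class_scores([inst.features for inst in instances])
    predicted = argmax_with_beta(rows, model.labels, beta=1.0)
    return dict(zip((inst.id for inst in instances), predicted))


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvaluationResult:
    """Instance-level precision / recall / F-score over positive labels."""

    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    fn: int
    empty_retrieved: bool = False


def evaluate(
    predicted: Mapping[str, str], gold: Mapping[str, str]
) -> EvaluationResult:
    """Set-intersection precision/recall/F over positively-labelled instances.

    Relevant = gold instances with a non-negative label; retrieved =
    predicted non-negative; a hit requires the same instance *and* the
    same label.  An empty retrieved set yields precision 0 (flagged).
    """
    if set(predicted) != set(gold):
        raise ValueError("predicted and gold cover different instance sets")
    retrieved = {k: v for k, v in predicted.items() if v != NEGATIVE_LABEL}
    relevant = {k: v for k, v in gold.items() if v != NEGATIVE_LABEL}
    tp = sum(1 for k, v in retrieved.items() if relevant.get(k) == v)
    fp = len(retrieved) - tp
    fn = len(relevant) - tp
    empty = len(retrieved) == 0
    precision = tp / len(retrieved) if retrieved else 0.0
    recall = tp / len(relevant) if relevant else 0.0
    f_score = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvaluationResult(
        precision=precision,
        recall=recall,
        f_score=f_score,
        tp=tp,
        fp=fp,
        fn=fn,
        empty_retrieved=empty,
    )


# ---------------------------------------------------------------------------
# fast path for combination experiments


class FeatureCache:
    """Per-class vectorised feature blocks for one train/devel split.

    Feature extraction and vectorisation are done once per feature class;
    evaluating a subset then reduces to a sparse horizontal stack and one
    classifier fit, which makes the 2^n - 1 subset sweep tractable.
    Vectoriser vocabularies are fitted on the training split only.
    """

    def __init__(
        self,
        train_corpus: Corpus,
        devel_corpus: Corpus,
        phase: str,
        class_ids: Sequence[FeatureClassId],
        window: int = 3,
        depth: int = 3,
    ):
        self.phase = phase
        self.class_ids = tuple(class_ids)
        extract = trigger_instances if phase == "trigger" else edge_instances
        kwargs = {"window": window, "depth": depth} if phase == "trigger" else {}
        self._blocks: dict[FeatureClassId, tuple[sp.spmatrix, sp.spmatrix]] = {}
        self.y_train: list[str] = []
        self.y_devel: list[str] = []
        self.devel_ids: list[str] = []
        for cid in self.class_ids:
            tr = extract(train_corpus, [cid], **kwargs)
            de = extract(devel_corpus, [cid], **kwargs)
            if not self.y_train:
                self.y_train = [i.gold for i in tr]
                self.y_devel = [i.gold for i in de]
                self.devel_ids = [i.id for i in de]
            vec = DictVectorizer(sparse=True)
            X_tr = vec.fit_transform([dict(i.features) for i in tr])
            X_de = vec.transform([dict(i.features) for i in de])
            self._blocks[cid] = (X_tr, X_de)

    def design(self, subset: Iterable[FeatureClassId]):
        """(X_train, X_devel, feature_size) for one class subset."""
        cids = sorted(subset, key=lambda c: (c.id, c.variant))
        blocks = [self._blocks[c] for c in cids]
        X_tr = sp.hstack([b[0] for b in blocks], format="csr")
        X_de = sp.hstack([b[1] for b in blocks], format="csr")
        return X_tr, X_de, X_tr.shape[1]


def make_subset_evaluator(cache: FeatureCache, config: DetectorConfig):
    """Evaluator for :func:`aee.combinations.run_experiment`.

    Maps a subset of feature-class *ids* (ints) or FeatureClassId objects
    to (devel F-score, feature size).
    """
    labels = TRIGGER_LABELS if cache.phase == "trigger" else EDGE_LABELS
    by_id = {}
    for cid in cache.class_ids:
        by_id[cid] = cid
        by_id[cid.id] = cid

    def evaluator(subset: frozenset) -> tuple[float, int]:
        cids = [by_id[s] for s in subset]
        X_tr, X_de, size = cache.design(cids)
        scorer = LogisticScorer(C=config.C, seed=config.seed).fit_matrix(
            X_tr, cache.y_train
        )
        rows = scorer.scores_matrix(X_de)
        beta = config.beta if cache.phase == "trigger" else 1.0
        predicted = argmax_with_beta(rows, labels, beta=beta)
        pred_map = dict(zip(cache.devel_ids, predicted))
        gold_map = dict(zip(cache.devel_ids, cache.y_devel))
        return evaluate(pred_map, gold_map).f_score, size

    return evaluator
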
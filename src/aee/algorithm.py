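"""Accumulated effect evaluation (AEE) of feature classes.

Given a ranking of feature-class subsets by classifier F-score (best
first), the occurrence ``O[i][j]`` of feature class ``i`` among the top
``j`` subsets is accumulated, and each class receives a score summed over
ranking prefixes:

* **AEE1**: ``AEE1(i) = sum_j O[i][j] / j`` — the prefix occurrence rate;
* **AEE2**: ``AEE2(i) = sum_j O[i][j] / T[j]`` with ``T[j]`` the total of
  all class occurrences in the top ``j`` subsets — which discounts large
  subsets, so a class carried by small, strong subsets scores higher.

Both scores are comparative; they are read against theoretical bounds over
all orderings of the complete subset lattice.  For AEE1 the bounds have a
closed form; for AEE2 they are computed on extremal arrangements (validated
by exhaustive permutation search at small n).

Scores and bounds operate on any ranking-like input: a
:class:`~aee.combinations.CombinationRanking`, or a plain sequence of
subsets of feature ids (already ordered best first).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "OccurrenceMatrix",
    "ContributionTable",
    "BoundsResult",
    "occurrence_matrix",
    "aee_scores",
    "aee1",
    "aee2",
    "aee1_bounds",
    "aee2_bounds",
    "bounds",
    "extremal_rankings",
    "average_contribution",
    "greedy_refine",
    "RefinementStep",
    "RefinementResult",
]


def _ranked_subsets(ranking) -> list[frozenset]:
    """Normalise ranking-like input to an ordered list of frozensets."""
    if hasattr(ranking, "subsets"):
        subs = list(ranking.subsets())
    else:
        subs = [frozenset(s) for s in ranking]
    if not subs:
        raise ValueError("ranking is empty")
    if any(not s for s in subs):
        raise ValueError("ranking contains an empty subset")
    return subs


@dataclass
class OccurrenceMatrix:
    """O[i][j]: occurrences of feature i among the top j subsets.

    ``features`` fixes the row order; ``O`` has shape (n_features, J) and
    ``T`` (column totals, i.e. cumulative subset sizes) has shape (J,).
    """

    features: tuple
    O: np.ndarray
    T: np.ndarray

    @property
    def J(self) -> int:
        return self.O.shape[1]

    def row(self, feature) -> np.ndarray:
        return self.O[self.features.index(feature)]


def occurrence_matrix(ranking, features: Sequence | None = None) -> OccurrenceMatrix:
    subs = _ranked_subsets(ranking)
    if features is None:
        features = sorted(set().union(*subs))
    indicator = np.array(
        [[f in s for s in subs] for f in features], dtype=np.int64
    )
    O = np.cumsum(indicator, axis=1)
    T = np.cumsum([len(s) for s in subs])
    return OccurrenceMatrix(features=tuple(features), O=O, T=np.asarray(T))


@dataclass
class ContributionTable:
    """Per-feature AEE scores for one ranking."""

    features: tuple
    aee1: dict
    aee2: dict
    J: int
    rates1: np.ndarray | None = field(default=None, repr=False)
    rates2: np.ndarray | None = field(default=None, repr=False)

    def best(self, method: str = "aee1"):
        scores = getattr(self, method)
        return max(scores, key=lambda f: (scores[f], _neg_key(f)))

    def worst(self, method: str = "aee1"):
        scores = getattr(self, method)
        return min(scores, key=lambda f: (scores[f], _neg_key(f)))


def _neg_key(f):
    # deterministic tie-break: prefer the smaller feature id
    return tuple(-ord(c) for c in str(f))


def aee_scores(ranking, features: Sequence | None = None) -> ContributionTable:
    """AEE1 and AEE2 scores of every feature class in the ranking."""
    occ = occurrence_matrix(ranking, features=features)
    j = np.arange(1, occ.J + 1, dtype=float)
    rates1 = occ.O / j
    rates2 = occ.O / occ.T.astype(float)
    s1 = rates1.sum(axis=1)
    s2 = rates2.sum(axis=1)
    return ContributionTable(
        features=occ.features,
        aee1=dict(zip(occ.features, s1.tolist())),
        aee2=dict(zip(occ.features, s2.tolist())),
        J=occ.J,
        rates1=rates1,
        rates2=rates2,
    )


def aee1(ranking, features: Sequence | None = None) -> dict:
    """AEE1(i) = sum over prefixes j of O[i][j] / j."""
    return aee_scores(ranking, features=features).aee1


def aee2(ranking, features: Sequence | None = None) -> dict:
    """AEE2(i) = sum over prefixes j of O[i][j] / T[j]."""
    return aee_scores(ranking, features=features).aee2


# ---------------------------------------------------------------------------
# theoretical bounds


def aee1_bounds(n: int) -> tuple[float, float]:
    """Closed-form (max, min) of AEE1 over complete rankings of n classes.

    The maximum is attained when all ``2^(n-1)`` subsets containing the
    focal class are ranked first; the minimum when they are ranked last.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    half = 2 ** (n - 1)
    total = 2**n - 1
    maximum = half + sum(Fraction(half, j) for j in range(half + 1, total + 1))
    minimum = sum(Fraction(k, half - 1 + k) for k in range(1, half + 1))
    return float(maximum), float(minimum)


def _all_subsets(n: int) -> list[frozenset[int]]:
    out = []
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(1, n + 1), size):
            out.append(frozenset(combo))
    return out


def extremal_rankings(
    n: int, focal: int = 1
) -> tuple[list[frozenset[int]], list[frozenset[int]]]:
    """(max, min) arrangements of the complete subset lattice for AEE2.

    Maximising: subsets containing the focal class first, in ascending
    size order, then the rest ascending.  Minimising: non-containing
    subsets first, then containing subsets in descending size order.
    Certified equal to exhaustive permutation extremes at small n in the
    test suite.
    """
    subs = _all_subsets(n)
    containing = sorted(
        (s for s in subs if focal in s), key=lambda s: (len(s), sorted(s))
    )
    rest = sorted(
        (s for s in subs if focal not in s), key=lambda s: (len(s), sorted(s))
    )
    maximal = containing + rest
    minimal = rest + sorted(
        containing, key=lambda s: (-len(s), sorted(s))
    )
    return maximal, minimal


def aee2_bounds(n: int) -> tuple[float, float]:
    """(max, min) of AEE2 over complete rankings, via extremal arrangements."""
    if n < 1:
        raise ValueError("n must be >= 1")
    maximal, minimal = extremal_rankings(n, focal=1)
    return aee2(maximal)[1], aee2(minimal)[1]


@dataclass
class BoundsResult:
    n: int
    max_aee1: float
    min_aee1: float
    max_aee2: float
    min_aee2: float


def bounds(n: int) -> BoundsResult:
    mx1, mn1 = aee1_bounds(n)
    mx2, mn2 = aee2_bounds(n)
    return BoundsResult(n=n, max_aee1=mx1, min_aee1=mn1, max_aee2=mx2, min_aee2=mn2)


# ---------------------------------------------------------------------------
# auxiliary analyses


def average_contribution(f_score: float, feature_size: int) -> float:
    """F-score (in percent) divided by the number of distinct features."""
    if feature_size < 1:
        raise ValueError("feature_size must be >= 1")
    return f_score / feature_size


# ---------------------------------------------------------------------------
# greedy refinement


@dataclass
class RefinementStep:
    """One accepted or rejected substitution round of the greedy search."""

    swapped: tuple
    best_subset: frozenset
    best_f: float
    accepted: bool


@dataclass
class RefinementResult:
    classes: dict
    ranking: object
    history: list[RefinementStep]
    warnings: list[str] = field(default_factory=list)

    @property
    def best_f(self) -> float:
        return self.ranking.results[0].f_score


def greedy_refine(
    ranking,
    variants: Mapping,
    rerun: Callable[[Mapping], object],
    classes: Mapping | None = None,
) -> RefinementResult:
    """Hill-climbing refinement of the feature-class configuration.

    The best- and worst-scoring classes of the current ranking (by AEE1,
    AEE2 breaking ties) are looked up in ``variants`` (class id ->
    replacement variant); available substitutions are applied and the
    combination experiment re-run via ``rerun(classes)``, which returns a
    new ranking.  A substitution round is kept while it improves the best
    F-score; the loop stops at the first non-improving round, so accepted
    refinements never decrease the development-split best F.
    """
    current = dict(classes) if classes is not None else {
        f: f for f in aee_scores(ranking).features
    }
    current_ranking = ranking
    history: list[RefinementStep] = []
    warnings: list[str] = []
    tried: set = set()
    while True:
        table = aee_scores(current_ranking)
        ordered = sorted(
            table.features,
            key=lambda f: (table.aee1[f], table.aee2[f]),
            reverse=True,
        )
        picks = [ordered[0], ordered[-1]]
        swap = tuple(
            f
            for f in picks
            if f in variants and current.get(f) != variants[f] and f not in tried
        )
        if not swap:
            if not history:
                warnings.append(
                    "no applicable variants for the best/worst classes; no-op"
                )
            break
        candidate = dict(current)
        for f in swap:
            candidate[f] = variants[f]
            tried.add(f)
        new_ranking = rerun(candidate)
        new_f = new_ranking.results[0].f_score
        accepted = new_f > current_ranking.results[0].f_score
        history.append(
            RefinementStep(
                swapped=swap,
                best_subset=new_ranking.results[0].subset,
                best_f=new_f,
                accepted=accepted,
            )
        )
        if not accepted:
            break
        current = candidate
        current_ranking = new_ranking
    return RefinementResult(
        classes=current, ranking=current_ranking, history=history, warnings=warnings
    )


def brute_force_aee2_extremes(n: int, focal: int = 1) -> tuple[float, float]:
    """Exhaustive AEE2 extremes over all permutations of the subset lattice.

    Only feasible for n <= 3 ((2^3 - 1)! = 5040 permutations); used to
    certify the constructive extremal arrangements.
    """
    subs = _all_subsets(n)
    best = -math.inf
    worst = math.inf
    for perm in itertools.permutations(subs):
        o = 0
        t = 0
        score = 0.0
        for s in perm:
            if focal in s:
                o += 1
            t += len(s)
            score += o / t
        best = max(best, score)
        worst = min(worst, score)
    return best, worst
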
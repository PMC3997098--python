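"""Exhaustive feature-class combination experiments.

Every nonempty subset of the feature classes is evaluated by a pluggable
evaluator (typically: train a detector with exactly those classes, score it
on the development split) and the subsets are ranked best-first by F-score.
The resulting :class:`CombinationRanking` is the substrate for accumulated
effect evaluation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence


@dataclass(frozen=True)
class CombinationResult:
    """One evaluated subset: the classes used, its F-score, its feature size."""

    subset: frozenset
    f_score: float
    size: int = 0

    def subset_label(self) -> str:
        """Subset rendered "1&2&4" style with prime variants as "4'"."""
        return "&".join(str(x) for x in sorted(self.subset, key=_order_key))


def _order_key(x):
    if hasattr(x, "id"):
        return (x.id, x.variant)
    return (int(x), "")


@dataclass
class CombinationRanking:
    """Subset results ordered best-first.

    Sort order: F-score descending, then smaller feature size, then
    lexicographic subset — fully deterministic.  ``failed`` lists subsets
    the evaluator could not score; they are excluded from the ranking, so
    a ranking may be incomplete (fewer than 2^n - 1 entries).
    """

    results: list[CombinationResult]
    n: int
    failed: list[tuple[frozenset, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.results = sorted(
            self.results,
            key=lambda r: (
                -r.f_score,
                r.size,
                tuple(sorted(_order_key(x) for x in r.subset)),
            ),
        )

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def complete(self) -> bool:
        return len(self.results) == 2**self.n - 1

    def subsets(self) -> list[frozenset]:
        return [r.subset for r in self.results]


def enumerate_subsets(classes: int | Sequence) -> list[frozenset]:
    """All 2^n - 1 nonempty subsets, ordered by size then lexicographically.

    ``classes`` is either the number of classes (ids 1..n) or an explicit
    sequence of class identifiers.
    """
    if isinstance(classes, int):
        if classes < 1:
            raise ValueError("need at least one feature class")
        items: list = list(range(1, classes + 1))
    else:
        items = sorted(classes, key=_order_key)
        if not items:
            raise ValueError("need at least one feature class")
    out: list[frozenset] = []
    for size in range(1, len(items) + 1):
        for combo in itertools.combinations(items, size):
            out.append(frozenset(combo))
    return out


class EvaluatorError(RuntimeError):
    """Raised by an evaluator to mark a subset as failed."""


def run_experiment(
    subsets: Iterable[frozenset],
    evaluator: Callable[[frozenset], tuple[float, int]],
    n: int | None = None,
    on_progress: Callable[[frozenset, float], None] | None = None,
) -> CombinationRanking:
    """Evaluate every subset and rank the results best-first.

    ``evaluator(subset)`` returns ``(f_score, feature_size)``; a raised
    :class:`EvaluatorError` records the subset as failed and excludes it
    from the ranking (incomplete rankings are scored against their actual
    length downstream).  The ranking is invariant to submission order.
    """
    subsets = list(subsets)
    if not subsets:
        raise ValueError("no subsets to evaluate")
    if n is None:
        n = len(set().union(*subsets))
    results: list[CombinationResult] = []
    failed: list[tuple[frozenset, str]] = []
    for subset in subsets:
        if not subset:
            raise ValueError("empty subset submitted")
        try:
            f_score, size = evaluator(frozenset(subset))
        except EvaluatorError as exc:
            failed.append((frozenset(subset), str(exc)))
            continue
        results.append(
            CombinationResult(subset=frozenset(subset), f_score=f_score, size=size)
        )
        if on_progress is not None:
            on_progress(frozenset(subset), f_score)
    return CombinationRanking(results=results, n=n, failed=failed)


def ranking_to_rows(ranking: CombinationRanking) -> list[dict]:
    """Flatten a ranking for TSV/JSON export ("1&2&4" subset labels)."""
    return [
        {
            "rank": i + 1,
            "subset": r.subset_label(),
            "f_score": round(100.0 * r.f_score, 2),
            "feature_size": r.size,
        }
        for i, r in enumerate(ranking.results)
    ]
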
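import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aee.algorithm import (
    aee1,
    aee1_bounds,
    aee2,
    aee2_bounds,
    aee_scores,
    average_contribution,
    bounds,
    brute_force_aee2_extremes,
    extremal_rankings,
    greedy_refine,
    occurrence_matrix,
)
from aee.combinations import CombinationRanking, CombinationResult, enumerate_subsets

RESULT_A = [{1, 2}, {1}, {2}]
RESULT_B = [{1}, {1, 2}, {2}]


def random_complete_ranking(n, rng):
    subsets = enumerate_subsets(n)
    rng.shuffle(subsets)
    return subsets


class TestOccurrenceMatrix:
    def test_result_a_columns(self):
        occ = occurrence_matrix(RESULT_A)
        assert occ.row(1).tolist() == [1, 2, 2]
        assert occ.row(2).tolist() == [1, 1, 2]
        assert occ.T.tolist() == [2, 3, 4]

    def test_single_subset(self):
        occ = occurrence_matrix([{1}])
        assert occ.row(1).tolist() == [1] and occ.T.tolist() == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_final_total_is_sum_of_subset_sizes(self, seed):
        rng = random.Random(seed)
        ranking = random_complete_ranking(4, rng)
        occ = occurrence_matrix(ranking)
        assert occ.T[-1] == sum(len(s) for s in ranking)

    def test_monotone_and_bounded(self):
        rng = random.Random(9)
        ranking = random_complete_ranking(5, rng)
        occ = occurrence_matrix(ranking)
        assert (np.diff(occ.O, axis=1) >= 0).all()
        assert (occ.O <= np.minimum(np.arange(1, occ.J + 1), 2**4)).all()
        assert (occ.O[:, -1] == 2**4).all()

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError):
            occurrence_matrix([])


class TestWorkedExamples:
    """The two printed 2-feature rankings and their eight AEE values."""

    def test_result_a(self):
        assert aee1(RESULT_A)[1] == pytest.approx(2.667, abs=5e-4)
        assert aee1(RESULT_A)[2] == pytest.approx(2.167, abs=5e-4)
        assert aee2(RESULT_A)[1] == pytest.approx(1.667, abs=5e-4)
        assert aee2(RESULT_A)[2] == pytest.approx(1.333, abs=5e-4)

    def test_result_b(self):
        assert aee1(RESULT_B)[1] == pytest.approx(2.667, abs=5e-4)
        assert aee1(RESULT_B)[2] == pytest.approx(1.167, abs=5e-4)
        assert aee2(RESULT_B)[1] == pytest.approx(2.167, abs=5e-4)
        assert aee2(RESULT_B)[2] == pytest.approx(0.833, abs=5e-4)

    def test_aee2_separates_what_aee1_cannot(self):
        # feature 1 carries the same AEE1 in both orderings but a higher
        # AEE2 when it appears alone at the top
        assert aee1(RESULT_A)[1] == pytest.approx(aee1(RESULT_B)[1])
        assert aee2(RESULT_B)[1] > aee2(RESULT_A)[1]

    def test_single_class_complete_ranking(self):
        assert aee1([{1}])[1] == pytest.approx(1.0)


class TestBounds:
    def test_aee1_bounds_printed_values(self):
        assert tuple(round(v, 2) for v in aee1_bounds(6)) == (53.43, 10.27)
        assert tuple(round(v, 2) for v in aee1_bounds(7)) == (107.61, 20.08)

    def test_aee1_bounds_degenerate(self):
        assert aee1_bounds(1) == (1.0, 1.0)

    def test_aee2_bounds_printed_values(self):
        assert tuple(round(v, 2) for v in aee2_bounds(6)) == (20.52, 3.28)
        assert tuple(round(v, 2) for v in aee2_bounds(7)) == (35.80, 5.54)

    def test_aee2_bounds_n2_worked_arrangement(self):
        mx, mn = aee2_bounds(2)
        assert mx == pytest.approx(2.167, abs=5e-4)
        assert mn == pytest.approx(0.833, abs=5e-4)

    @pytest.mark.parametrize("n", [2, 3])
    def test_constructive_extremes_match_exhaustive_search(self, n):
        brute_max, brute_min = brute_force_aee2_extremes(n)
        mx, mn = aee2_bounds(n)
        assert mx == pytest.approx(brute_max)
        assert mn == pytest.approx(brute_min)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            aee1_bounds(0)
        with pytest.raises(ValueError):
            aee2_bounds(0)


class TestInvariants:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_aee2_normalisation(self, n):
        rng = random.Random(n)
        for _ in range(20):
            ranking = random_complete_ranking(n, rng)
            total = sum(aee2(ranking).values())
            assert total == pytest.approx(2**n - 1)

    @pytest.mark.parametrize("n", [4, 5])
    def test_scores_within_bounds_random_permutations(self, n):
        rng = random.Random(n)
        mx1, mn1 = aee1_bounds(n)
        mx2, mn2 = aee2_bounds(n)
        for _ in range(50):
            ranking = random_complete_ranking(n, rng)
            table = aee_scores(ranking)
            for f in table.features:
                assert mn1 - 1e-9 <= table.aee1[f] <= mx1 + 1e-9
                assert mn2 - 1e-9 <= table.aee2[f] <= mx2 + 1e-9

    def test_relabelling_symmetry(self):
        rng = random.Random(17)
        ranking = random_complete_ranking(4, rng)
        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        relabelled = [{perm[x] for x in s} for s in ranking]
        before = aee_scores(ranking)
        after = aee_scores(relabelled)
        for f in (1, 2, 3, 4):
            assert after.aee1[perm[f]] == pytest.approx(before.aee1[f])
            assert after.aee2[perm[f]] == pytest.approx(before.aee2[f])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=5),
        order_seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_bounds_and_normalisation_hold_for_any_complete_ranking(
        self, n, order_seed
    ):
        ranking = random_complete_ranking(n, random.Random(order_seed))
        table = aee_scores(ranking)
        mx1, mn1 = aee1_bounds(n)
        mx2, mn2 = aee2_bounds(n)
        assert sum(table.aee2.values()) == pytest.approx(2**n - 1)
        for f in table.features:
            assert mn1 - 1e-9 <= table.aee1[f] <= mx1 + 1e-9
            assert mn2 - 1e-9 <= table.aee2[f] <= mx2 + 1e-9

    def test_incomplete_ranking_scored_over_actual_length(self):
        # drop one subset from a complete 2-class ranking
        table = aee_scores([{1, 2}, {1}])
        assert table.J == 2
        assert sum(table.aee2.values()) == pytest.approx(2)


class TestAverageContribution:
    def test_printed_lexical_row(self):
        assert round(average_contribution(6.43, 154), 5) == 0.04175

    def test_printed_content_class(self):
        assert average_contribution(27.11, 8573) == pytest.approx(0.003, abs=2e-4)

    def test_zero_f_score(self):
        assert average_contribution(0.0, 10) == 0.0

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            average_contribution(1.0, 0)


def make_ranking(scores, n):
    results = [
        CombinationResult(subset=frozenset(s), f_score=f, size=len(s))
        for s, f in scores.items()
    ]
    return CombinationRanking(results=results, n=n)


class TestGreedyRefine:
    def test_substitution_triggered_and_accepted(self):
        subsets = enumerate_subsets(2)
        base_scores = {s: 0.5 + 0.1 * (1 in s) for s in subsets}
        improved = {s: f + 0.2 for s, f in base_scores.items()}
        ranking = make_ranking(base_scores, 2)
        calls = []

        def rerun(classes):
            calls.append(dict(classes))
            return make_ranking(improved, 2)

        result = greedy_refine(
            ranking, variants={1: "1'"}, rerun=rerun, classes={1: "1", 2: "2"}
        )
        assert calls and calls[0][1] == "1'"
        assert result.history[0].accepted
        assert result.classes[1] == "1'"
        assert result.best_f > ranking.results[0].f_score

    def test_accepted_refinements_never_decrease_best_f(self):
        subsets = enumerate_subsets(3)
        rng = random.Random(2)
        scores = {s: rng.random() for s in subsets}
        ranking = make_ranking(scores, 3)
        level = {"v": 0}

        def rerun(classes):
            # each variant adoption adds a small improvement
            level["v"] += 0.05
            return make_ranking(
                {s: min(1.0, f + level["v"]) for s, f in scores.items()}, 3
            )

        result = greedy_refine(
            ranking,
            variants={1: "1'", 2: "2'", 3: "3'"},
            rerun=rerun,
            classes={1: "1", 2: "2", 3: "3"},
        )
        best = ranking.results[0].f_score
        for step in result.history:
            if step.accepted:
                assert step.best_f >= best
                best = step.best_f

    def test_no_variant_is_noop_with_warning(self):
        ranking = make_ranking({frozenset({1}): 0.5}, 1)
        result = greedy_refine(ranking, variants={}, rerun=lambda c: ranking)
        assert result.history == []
        assert result.warnings

    def test_non_improving_variant_single_pass(self):
        subsets = enumerate_subsets(2)
        scores = {s: 0.5 + 0.1 * (1 in s) for s in subsets}
        ranking = make_ranking(scores, 2)
        calls = []

        def rerun(classes):
            calls.append(1)
            return make_ranking({s: f - 0.1 for s, f in scores.items()}, 2)

        result = greedy_refine(
            ranking, variants={1: "1'", 2: "2'"}, rerun=rerun, classes={1: "1", 2: "2"}
        )
        assert len(calls) == 1
        assert not result.history[0].accepted
        assert result.classes == {1: "1", 2: "2"}
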
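import itertools

import numpy as np
import pandas as pd
import pytest

from reopair import (
    ExpressionMatrix,
    MiRPair,
    ValidationError,
    activity_scores,
    combination_coverage,
    grow_combination,
    sample_covered,
    select_top_k,
)
from reopair.coverage import ActivityRanking

from conftest import brute_force_coverage


def _matrix_from_cover_sets(cover_sets: dict, n_samples: int):
    """Build a control-only matrix where pair p covers exactly the given
    sample indices.  Pair p_i is (ai, bi); ai > bi on covered samples."""
    features = []
    rows = {}
    pairs = []
    for name, covered in cover_sets.items():
        a, b = f"{name}_hi", f"{name}_lo"
        pairs.append(MiRPair(a, b))
        rows[a] = [10.0 if j in covered else 1.0 for j in range(n_samples)]
        rows[b] = [5.0] * n_samples
        features += [a, b]
    data = pd.DataFrame(
        rows, index=[f"s{j}" for j in range(n_samples)]
    ).T.loc[features]
    labels = {f"s{j}": "ctrl" for j in range(n_samples)}
    return ExpressionMatrix(data, labels), pairs, labels


class TestSampleCovered:
    def test_reference_pattern(self):
        vec = {"a": 5.0, "b": 3.0}
        p = MiRPair("a", "b")
        assert sample_covered(vec, "ctrl", p, "ctrl", "case") is True
        assert sample_covered(vec, "case", p, "ctrl", "case") is False

    def test_tie_counts_toward_case_pattern(self):
        vec = {"a": 4.0, "b": 4.0}
        p = MiRPair("a", "b")
        assert sample_covered(vec, "case", p, "ctrl", "case") is True
        assert sample_covered(vec, "ctrl", p, "ctrl", "case") is False

    def test_unlabeled_sample_is_error(self):
        with pytest.raises(ValidationError, match="neither"):
            sample_covered(
                {"a": 1.0, "b": 2.0}, "other", MiRPair("a", "b"), "ctrl", "case"
            )


class TestCombinationCoverage:
    def test_disjoint_halves(self):
        m, pairs, labels = _matrix_from_cover_sets(
            {"p1": {0, 1}, "p2": {2, 3}}, n_samples=4
        )
        assert combination_coverage(pairs, m, labels, "ctrl", "case") == 1.0
        assert combination_coverage(pairs[:1], m, labels, "ctrl", "case") == 0.5
        assert combination_coverage(pairs[1:], m, labels, "ctrl", "case") == 0.5

    def test_empty_members_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError, match="empty"):
            combination_coverage(
                [], tiny_matrix, tiny_matrix.labels, "control", "case"
            )

    def test_all_subsets_match_brute_force(self):
        rng = np.random.default_rng(17)
        n_samples = 12
        cover_sets = {
            f"p{i}": set(
                rng.choice(n_samples, size=rng.integers(1, 7), replace=False)
            )
            for i in range(6)
        }
        m, pairs, labels = _matrix_from_cover_sets(cover_sets, n_samples)
        for r in range(1, len(pairs) + 1):
            for subset in itertools.combinations(pairs, r):
                got = combination_coverage(
                    list(subset), m, labels, "ctrl", "case"
                )
                want = brute_force_coverage(subset, m, labels, "ctrl", "case")
                assert got == pytest.approx(want)


class TestGrowCombination:
    def test_seed_covering_all_stops_immediately(self):
        m, pairs, labels = _matrix_from_cover_sets(
            {"full": {0, 1, 2, 3}, "half": {0, 1}}, n_samples=4
        )
        combo = grow_combination(pairs[0], pairs, m, labels, "ctrl", "case")
        assert combo.members == [pairs[0]]
        assert combo.coverage == 1.0

    def test_hand_enumerable_growth(self):
        # cover sets {s0,s1}, {s2}, {s2,s3}: from the first seed the greedy
        # step adds the third pair (gain 2 beats gain 1) and reaches 1.0
        m, pairs, labels = _matrix_from_cover_sets(
            {"p1": {0, 1}, "p2": {2}, "p3": {2, 3}}, n_samples=4
        )
        combo = grow_combination(pairs[0], pairs, m, labels, "ctrl", "case")
        assert combo.members == [pairs[0], pairs[2]]
        assert combo.coverage == 1.0

    def test_seed_must_be_candidate(self, tiny_matrix):
        with pytest.raises(ValidationError, match="not a candidate"):
            grow_combination(
                MiRPair("f1", "f2"),
                [MiRPair("f1", "f3")],
                tiny_matrix,
                tiny_matrix.labels,
                "control",
                "case",
            )

    def test_history_strictly_increasing_and_locally_optimal(self):
        rng = np.random.default_rng(23)
        n_samples = 12
        cover_sets = {
            f"p{i}": set(
                rng.choice(n_samples, size=rng.integers(1, 8), replace=False)
            )
            for i in range(8)
        }
        m, pairs, labels = _matrix_from_cover_sets(cover_sets, n_samples)
        for seed in pairs:
            combo = grow_combination(seed, pairs, m, labels, "ctrl", "case")
            assert all(
                b > a for a, b in zip(combo.history, combo.history[1:])
            )
            # no single further addition can improve coverage
            for extra in set(pairs) - set(combo.members):
                aug = combination_coverage(
                    combo.members + [extra], m, labels, "ctrl", "case"
                )
                assert aug <= combo.coverage + 1e-12


class TestActivityScores:
    def test_single_candidate_scores_one(self):
        m, pairs, labels = _matrix_from_cover_sets({"p1": {0, 1}}, 3)
        ranking = activity_scores(pairs, m, labels, "ctrl", "case")
        assert ranking.scores == {pairs[0]: 1}

    def test_universal_pair_in_every_combination(self):
        # one pair covering everything is added to every other seed's
        # combination, so its score is n_candidates
        m, pairs, labels = _matrix_from_cover_sets(
            {"u": {0, 1, 2, 3}, "a": {0}, "b": {1}, "c": {2}}, n_samples=4
        )
        ranking = activity_scores(pairs, m, labels, "ctrl", "case")
        assert ranking.scores[pairs[0]] == 4
        assert ranking.order[0] == pairs[0]

    def test_scores_conserve_total_memberships(self):
        rng = np.random.default_rng(31)
        n_samples = 10
        cover_sets = {
            f"p{i}": set(
                rng.choice(n_samples, size=rng.integers(1, 6), replace=False)
            )
            for i in range(7)
        }
        m, pairs, labels = _matrix_from_cover_sets(cover_sets, n_samples)
        ranking = activity_scores(pairs, m, labels, "ctrl", "case")
        total = 0
        for seed in pairs:
            combo = grow_combination(seed, pairs, m, labels, "ctrl", "case")
            total += len(combo.members)
        assert sum(ranking.scores.values()) == total
        assert all(
            1 <= s <= len(pairs) for s in ranking.scores.values()
        )

    def test_deterministic(self):
        rng = np.random.default_rng(41)
        n_samples = 10
        cover_sets = {
            f"p{i}": set(
                rng.choice(n_samples, size=rng.integers(1, 6), replace=False)
            )
            for i in range(6)
        }
        m, pairs, labels = _matrix_from_cover_sets(cover_sets, n_samples)
        r1 = activity_scores(pairs, m, labels, "ctrl", "case")
        r2 = activity_scores(pairs, m, labels, "ctrl", "case")
        assert r1.scores == r2.scores
        assert r1.order == r2.order


def _two_group_matrix(seed: int, n_perfect: int = 5, n_noisy: int = 6,
                      n_ctrl: int = 15, n_case: int = 15):
    """Pairs 1..n_perfect fully reverse between groups; the rest are noise."""
    rng = np.random.default_rng(seed)
    n = n_ctrl + n_case
    rows = {}
    pairs = []
    for i in range(n_perfect):
        a, b = f"g{i}_hi", f"g{i}_lo"
        pairs.append(MiRPair(a, b))
        rows[a] = [10.0] * n_ctrl + [1.0] * n_case
        rows[b] = [5.0] * n
    for i in range(n_noisy):
        a, b = f"z{i}_hi", f"z{i}_lo"
        pairs.append(MiRPair(a, b))
        va = rng.uniform(1, 10, size=n)
        rows[a] = list(va)
        rows[b] = [5.0] * n
    data = pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T
    labels = {
        f"s{j}": ("ctrl" if j < n_ctrl else "case") for j in range(n)
    }
    return ExpressionMatrix(data, labels), pairs, labels


class TestSelectTopK:
    def test_single_perfect_pair_gives_k1(self):
        m, pairs, labels = _two_group_matrix(seed=1, n_perfect=1, n_noisy=0)
        ranking = ActivityRanking(scores={pairs[0]: 1}, order=pairs)
        model, curve = select_top_k(ranking, m, labels, "ctrl", "case")
        assert len(model.pairs) == 1
        assert curve.loc[0, "geometric_mean"] == 1.0

    def test_perfect_pairs_first_reach_max_small_k(self):
        m, pairs, labels = _two_group_matrix(seed=2)
        ranking = activity_scores(pairs, m, labels, "ctrl", "case")
        model, curve = select_top_k(ranking, m, labels, "ctrl", "case")
        assert len(model.pairs) <= 5
        best = curve["geometric_mean"].max()
        assert best == 1.0
        # the chosen k is the smallest one attaining the global max
        first_max_k = int(
            curve.loc[curve["geometric_mean"] == best, "k"].min()
        )
        assert len(model.pairs) == first_max_k

    def test_curve_matches_brute_force_scan(self):
        m, pairs, labels = _two_group_matrix(seed=3)
        ranking = activity_scores(pairs, m, labels, "ctrl", "case")
        model, curve = select_top_k(ranking, m, labels, "ctrl", "case")
        from reopair import VotingModel, evaluate, predict_matrix

        for _, row in curve.iterrows():
            k = int(row["k"])
            mk = VotingModel.majority(ranking.order[:k], "ctrl", "case")
            metrics = evaluate(
                predict_matrix(mk, m), labels, "case"
            )
            assert row["geometric_mean"] == pytest.approx(
                metrics.geometric_mean
            )
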
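"""Relaxed match, rank metrics against brute-force oracles, CV folds and
the paired t test."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focusrank.evaluation import (
    auc_ke,
    auc_ranking,
    make_folds,
    paired_t_test,
    prf_at_k,
    relaxed_match,
)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_auc(scores, labels):
    """Pair counting: concordant pairs + half the ties."""
    total = good = 0
    for i, (si, yi) in enumerate(zip(scores, labels)):
        if yi != 1:
            continue
        for sj, yj in zip(scores, labels):
            if yj != 0:
                continue
            total += 1
            if si > sj:
                good += 1
            elif si == sj:
                good += 0.5
    return good / total


def brute_force_prf(ranked, gold, k):
    """One-credit-per-gold counting with exact-equality matching."""
    credited = set()
    tp = 0
    for term in ranked[:k]:
        for g in gold:
            if g not in credited and term == g:
                credited.add(g)
                tp += 1
                break
    p = tp / k
    r = tp / len(gold)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


class TestRelaxedMatch:
    @pytest.mark.parametrize(
        ("system", "gold", "expected"),
        [
            ("non-Hodgkin lymphoma", "lymphoma", True),   # subsume
            ("disease", "Crohn's disease", False),        # part-of
            ("iron", "iron deficiency", False),           # part-of
            ("Crohn disease", "crohn's disease", True),   # equal after normalisation
            ("Diabetes Mellitus", "diabetes mellitus", True),
            ("running pains", "run pain", True),          # stemming
            ("lymphoma", "hodgkin lymphoma", False),
            ("", "lymphoma", False),
            ("lymphoma", "", False),
        ],
    )
    def test_decisions(self, system, gold, expected):
        assert relaxed_match(system, gold) is expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from("abc def ghi jkl".split()), min_size=1, max_size=4))
    def test_reflexive_and_antisymmetric(self, words):
        term = " ".join(words)
        assert relaxed_match(term, term)
        longer = term + " xyz"
        assert relaxed_match(longer, term)
        assert not relaxed_match(term, longer)


class TestPRFAtK:
    def test_all_top5_hit_large_gold(self):
        gold = [f"g{i}" for i in range(10)]
        p, r, f = prf_at_k(gold[:5], gold, 5)
        assert (p, r) == (1.0, 0.5)
        assert f == pytest.approx(2 / 3)

    def test_partial_hits(self):
        ranked = ["g0", "x", "g1", "y", "z"]
        p, r, f = prf_at_k(ranked, ["g0", "g1", "g2", "g3"], 5)
        assert (p, r) == (0.4, 0.5)
        assert f == pytest.approx(4 / 9)

    def test_short_list_no_hits(self):
        assert prf_at_k(["x"], ["gold"], 5) == (0.0, 0.0, 0.0)

    def test_duplicate_system_term_single_credit(self):
        p, r, _ = prf_at_k(["g0", "g0", "g0", "x", "y"], ["g0"], 5)
        assert p == pytest.approx(0.2)
        assert r == 1.0

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            prf_at_k(["x"], [], 5)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        universe = [f"t{i}" for i in range(12)]
        for _ in range(200):
            gold = list(rng.choice(universe, size=rng.integers(1, 6), replace=False))
            ranked = list(rng.choice(universe, size=rng.integers(1, 12), replace=False))
            for k in (5, 10):
                assert prf_at_k(ranked, gold, k) == pytest.approx(
                    brute_force_prf(ranked, gold, k), abs=1e-12
                )

    def test_recall_monotone_in_k(self):
        rng = np.random.default_rng(5)
        universe = [f"t{i}" for i in range(15)]
        for _ in range(50):
            gold = list(rng.choice(universe, size=4, replace=False))
            ranked = list(rng.permutation(universe))
            _, r5, _ = prf_at_k(ranked, gold, 5)
            _, r10, _ = prf_at_k(ranked, gold, 10)
            assert r10 >= r5


class TestAUC:
    def test_worked_example(self):
        assert auc_ranking([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_and_all_tied(self):
        assert auc_ranking([3, 2, 1], [1, 1, 0]) == 1.0
        assert auc_ranking([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_ranking([0.1, 0.9], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 21))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantised scores so ties actually occur
            scores = rng.integers(0, 6, size=n) / 5.0
            assert auc_ranking(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestAUCKE:
    def test_decomposition_identity(self):
        """auc_ke = auc_ranking * found/(found+missed) without phantom ties."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 16))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.normal(size=n)  # continuous: no ties
            missed = int(rng.integers(1, 4))
            found = int(labels.sum())
            expected = auc_ranking(scores, labels) * found / (found + missed)
            assert auc_ke(scores, labels, missed) == pytest.approx(expected, abs=1e-12)

    def test_worked_decomposition(self):
        scores = list(range(10, 0, -1))
        labels = [1] * 9 + [0]
        base = auc_ranking(scores, labels)
        assert auc_ke(scores, labels, 1) == pytest.approx(base * 9 / 10)

    def test_no_misses_reduces_to_ranking_auc(self):
        scores, labels = [0.9, 0.2, 0.4], [1, 0, 1]
        assert auc_ke(scores, labels, 0) == auc_ranking(scores, labels)

    def test_upper_bounded_by_ranking_auc(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            scores = rng.normal(size=10)
            labels = rng.integers(0, 2, size=10)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_ke(scores, labels, 2) < auc_ranking(scores, labels)

    def test_all_gold_missed_degenerate(self):
        with pytest.raises(ValueError):
            auc_ke([0.5, 0.4], [0, 0], 2)  # no scored positives


class TestPairedTTest:
    def test_identical_vectors(self):
        p, degenerate = paired_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert p == 1.0 and degenerate

    def test_constant_nonzero_difference(self):
        p, degenerate = paired_t_test([0.2] * 4, [0.1] * 4)
        assert p == 0.0 and degenerate

    def test_matches_scipy_on_regular_data(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a, b = rng.normal(size=20), rng.normal(size=20)
        p, degenerate = paired_t_test(a, b)
        assert not degenerate
        assert p == pytest.approx(stats.ttest_rel(a, b).pvalue)

    def test_null_calibration(self):
        """Under the null, the rejection rate at alpha=.05 is about 5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            p, _ = paired_t_test(a, b)
            rejections += p < 0.05
        # binomial(200, .05): central 99.9% region is roughly [1, 21]
        assert 1 <= rejections <= 21


class TestMakeFolds:
    def test_balanced_partition(self):
        ids = [f"note_{i:03d}" for i in range(90)]
        folds = make_folds(ids, 10, seed=1)
        counts = np.bincount(list(folds.values()))
        assert (counts == 9).all()

    def test_deterministic(self):
        ids = [f"n{i}" for i in range(20)]
        assert make_folds(ids, 4, seed=9) == make_folds(ids, 4, seed=9)
        assert make_folds(ids, 4, seed=9) != make_folds(ids, 4, seed=10)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 3, seed=0)
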
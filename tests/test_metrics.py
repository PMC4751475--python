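"""Evaluation measures: matching, F1, geometric accuracy, MMR, composite."""

import itertools
import math

import numpy as np
import pytest

import epcomplex as ep


def brute_force_mmr(S, P):
    """Enumerate all one-to-one matchings; tractable for <=7 per side."""
    S, P = list(S), list(P)
    weights = [[ep.overlap_score(s, p) for p in P] for s in S]
    best = 0.0
    n, m = len(S), len(P)
    k = min(n, m)
    for r in range(k + 1):
        for rows in itertools.combinations(range(n), r):
            for cols in itertools.permutations(range(m), r):
                best = max(best, sum(weights[i][j] for i, j in zip(rows, cols)))
    return best / len(S)


class TestMatchSets:
    def test_exact_prediction(self):
        S = [frozenset("abc"), frozenset("defg")]
        st, sp = ep.match_sets(S, S)
        assert st == S and sp == S

    def test_boundary_quarter_is_inclusive(self):
        s, p = frozenset("abcd"), frozenset("cdef")
        st, sp = ep.match_sets([s], [p])
        assert st == [s] and sp == [p]

    def test_disjoint(self):
        st, sp = ep.match_sets([frozenset("ab")], [frozenset("cd")])
        assert st == [] and sp == []

    def test_empty_inputs_warn_not_raise(self):
        assert ep.match_sets([], [frozenset("ab")]) == ([], [])


class TestPrecisionRecallF1:
    def test_toy_counts(self):
        # |S|=4, |P|=5, |St|=2, |Sp|=3
        S = [frozenset({f"s{i}", f"t{i}", f"u{i}"}) for i in range(4)]
        P = [frozenset({f"p{i}", f"q{i}", f"r{i}"}) for i in range(5)]
        S[0], S[1] = frozenset("abc"), frozenset("def")
        P[0], P[1], P[2] = frozenset("abc"), frozenset("abd"), frozenset("def")
        precision, recall, f1 = ep.precision_recall_f1(S, P)
        assert precision == pytest.approx(0.6)
        assert recall == pytest.approx(0.5)
        assert f1 == pytest.approx(2 * 0.6 * 0.5 / 1.1)

    def test_perfect(self):
        S = [frozenset("abc")]
        assert ep.precision_recall_f1(S, S) == (1.0, 1.0, 1.0)

    def test_no_matches(self):
        assert ep.precision_recall_f1([frozenset("ab")],
                                      [frozenset("xy")]) == (0.0, 0.0, 0.0)


class TestGeometricAccuracy:
    def test_printed_toy(self):
        sen, ppv, acc = ep.geometric_accuracy([frozenset("abc")], [frozenset("ab")])
        assert sen == pytest.approx(2 / 3)
        assert ppv == pytest.approx(1.0)
        assert acc == pytest.approx(math.sqrt(2 / 3))

    def test_perfect(self):
        S = [frozenset("abc"), frozenset("de")]
        assert ep.geometric_accuracy(S, S) == (1.0, 1.0, 1.0)

    def test_disjoint_gives_zero(self):
        sen, ppv, acc = ep.geometric_accuracy([frozenset("ab")], [frozenset("xy")])
        assert (sen, ppv, acc) == (0.0, 0.0, 0.0)

    def test_acc_squared_identity(self):
        rng = np.random.default_rng(0)
        universe = [f"x{i}" for i in range(20)]
        for _ in range(20):
            S = [frozenset(rng.choice(universe, size=rng.integers(2, 6),
                                      replace=False)) for _ in range(4)]
            P = [frozenset(rng.choice(universe, size=rng.integers(2, 6),
                                      replace=False)) for _ in range(5)]
            sen, ppv, acc = ep.geometric_accuracy(S, P)
            assert acc * acc == pytest.approx(sen * ppv)


class TestMaximumMatchingRatio:
    def test_one_prediction_two_references(self):
        # omega(s1,p)=0.5, omega(s2,p)=0.9: the matching keeps only the
        # 0.9 edge, so MMR = 0.9 / |S| = 0.45
        p = frozenset(range(10))
        s1 = frozenset(range(5))   # 25/(5*10) = 0.5
        s2 = frozenset(range(9))   # 81/(9*10) = 0.9
        assert ep.overlap_score(s1, p) == pytest.approx(0.5)
        assert ep.overlap_score(s2, p) == pytest.approx(0.9)
        assert ep.maximum_matching_ratio([s1, s2], [p]) == pytest.approx(0.45)

    def test_winner_take_best_edge(self):
        # weights via real sets: s2 matches p perfectly (1.0), s1 partially
        s1, s2 = frozenset("abcd"), frozenset("cdef")
        p = frozenset("cdef")
        assert ep.maximum_matching_ratio([s1, s2], [p]) == pytest.approx(0.5)

    def test_perfect(self):
        S = [frozenset("abc"), frozenset("def")]
        assert ep.maximum_matching_ratio(S, S) == 1.0

    def test_no_overlap(self):
        assert ep.maximum_matching_ratio([frozenset("ab")], [frozenset("xy")]) == 0.0

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        universe = [f"x{i}" for i in range(12)]
        for _ in range(40):
            n, m = rng.integers(1, 8), rng.integers(1, 8)
            S = [frozenset(rng.choice(universe, size=rng.integers(2, 5),
                                      replace=False)) for _ in range(n)]
            P = [frozenset(rng.choice(universe, size=rng.integers(2, 5),
                                      replace=False)) for _ in range(m)]
            assert ep.maximum_matching_ratio(S, P) == pytest.approx(
                brute_force_mmr(S, P))


class TestEvaluate:
    def test_perfect_composite(self):
        S = [frozenset("abc"), frozenset("defg")]
        rep = ep.evaluate(S, S)
        assert rep.composite == pytest.approx(3.0)
        assert rep.acc == 1.0 and rep.mmr == 1.0 and rep.recall == 1.0

    def test_components_consistent(self):
        S = [frozenset("abc")]
        P = [frozenset("ab")]
        rep = ep.evaluate(S, P)
        assert rep.sen == pytest.approx(2 / 3)
        assert rep.ppv == pytest.approx(1.0)
        assert rep.acc == pytest.approx(math.sqrt(2 / 3))
        assert rep.composite == pytest.approx(rep.recall + rep.acc + rep.mmr)
        assert rep.acc ** 2 == pytest.approx(rep.sen * rep.ppv)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        universe = [f"x{i}" for i in range(15)]
        S = [frozenset(rng.choice(universe, size=4, replace=False))
             for _ in range(3)]
        P = [frozenset(rng.choice(universe, size=4, replace=False))
             for _ in range(4)]
        a, b = ep.evaluate(S, P), ep.evaluate(P, S)
        # omega is symmetric, so the matched-set measures swap exactly;
        # sen/ppv do not swap in general because their denominators differ
        # (reference sizes vs total intersection mass)
        assert a.precision == pytest.approx(b.recall)
        assert a.recall == pytest.approx(b.precision)
        assert a.f1 == pytest.approx(b.f1)
        assert a.mmr * a.n_reference == pytest.approx(b.mmr * b.n_reference)

    def test_adding_unmatched_prediction_only_hurts_precision_ppv(self):
        S = [frozenset("abcd"), frozenset("efgh")]
        P = [frozenset("abcd")]
        before = ep.evaluate(S, P)
        after = ep.evaluate(S, P + [frozenset("wxyz")])
        assert after.precision <= before.precision
        assert after.ppv <= before.ppv
        assert after.recall == before.recall
        assert after.mmr == before.mmr

    def test_report_fields_in_range(self, dense_benchmark):
        b = dense_benchmark
        pred = b["detector"].predict(b["network"], attributes=b["attributes"])
        rep = ep.evaluate(b["test"], pred)
        d = rep.to_dict()
        for key in ("precision", "recall", "f1", "sen", "ppv", "acc", "mmr"):
            assert 0 <= d[key] <= 1
        assert 0 <= rep.composite <= 3
        assert "precision" in rep.to_tsv()
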
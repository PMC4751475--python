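"""Noise-tolerant emerging-pattern mining against the brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epcomplex as ep
from epcomplex.mining import NEP

from conftest import random_item_dataset


class TestSupport:
    def test_full_and_partial_support(self):
        data = [(0, 1), (0, 1), (0, 2), (0, 0)]
        assert ep.support({(0, 0)}, data) == 1.0   # feature 0 is bin 0 everywhere
        assert ep.support({(1, 1)}, data) == pytest.approx(0.5)
        assert ep.support({(0, 0), (1, 9)}, data) == 0.0

    def test_empty_itemset_is_vacuous(self):
        assert ep.support(set(), [(1, 2)]) == 1.0

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            ep.support({(0, 0)}, [])

    def test_antimonotone(self):
        rng = np.random.default_rng(0)
        data = random_item_dataset(rng, 5, 3, 30)
        for _ in range(50):
            n = rng.integers(1, 5)
            feats = rng.choice(5, size=n, replace=False)
            items = {(int(f), int(rng.integers(0, 3))) for f in feats}
            sub = set(itertools.islice(items, len(items) - 1))
            assert ep.support(sub, data) >= ep.support(items, data)


class TestMineNeps:
    def test_single_perfect_item(self):
        target = [(0,)] * 4
        background = [(1,)] * 4
        neps = ep.mine_neps(background, target, 0.1, 0.7)
        assert neps == {NEP(frozenset({(0, 0)}), 1.0, 0.0)}

    def test_identical_classes_yield_nothing(self):
        data = [(0, 1), (1, 0), (0, 0)]
        assert ep.mine_neps(data, data, 0.1, 0.7) == set()

    def test_pair_pattern_where_singletons_fail(self):
        # items b=(0,1), c=(1,1): each common in background, the pair rare
        background = ([(1, 0)] * 10 + [(0, 1)] * 9 + [(1, 1)] * 1)
        target = [(1, 1)] * 16 + [(0, 0)] * 4
        neps = ep.mine_neps(background, target, delta1=0.1, delta2=0.7)
        pair = frozenset({(0, 1), (1, 1)})
        assert pair in {n.items for n in neps}
        assert frozenset({(0, 1)}) not in {n.items for n in neps}
        assert frozenset({(1, 1)}) not in {n.items for n in neps}
        assert neps == ep.brute_force_neps(background, target, 0.1, 0.7)

    def test_invalid_thresholds(self):
        data = [(0,)]
        with pytest.raises(ValueError):
            ep.mine_neps(data, data, 0.7, 0.7)
        with pytest.raises(ValueError):
            ep.mine_neps(data, data, 0.5, 0.2)

    def test_supports_attached(self):
        background = [(0, 0)] * 20
        target = [(1, 1)] * 9 + [(0, 0)] * 1
        neps = ep.mine_neps(background, target, 0.1, 0.7)
        assert {n.items for n in neps} == {frozenset({(0, 1)}),
                                           frozenset({(1, 1)})}
        for nep in neps:
            assert nep.support_target == pytest.approx(0.9)
            assert nep.support_background == 0.0

    def test_minimality_no_nested_outputs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            bg = random_item_dataset(rng, 4, 3, 25)
            tg = random_item_dataset(rng, 4, 3, 25)
            neps = ep.mine_neps(bg, tg, 0.15, 0.6)
            sets = [n.items for n in neps]
            for a, b in itertools.combinations(sets, 2):
                assert not (a < b or b < a)


class TestBruteForceOracle:
    def test_universe_guard(self):
        big = [tuple(range(30))]
        with pytest.raises(ValueError, match="oracle"):
            ep.brute_force_neps(big, big, 0.1, 0.7)

    def test_delta1_zero_limit(self):
        # delta1 -> 0+ : only itemsets absent from background qualify
        background = [(0, 0), (0, 1)]
        target = [(1, 1)] * 4
        neps = ep.brute_force_neps(background, target, 1e-9, 1.0)
        for n in neps:
            assert ep.support(n.items, background) == 0.0
        assert frozenset({(0, 1)}) in {n.items for n in neps}

    def test_delta2_one_limit(self):
        background = [(0, 0)] * 10
        target = [(1, 1), (1, 2)]
        neps = ep.brute_force_neps(background, target, 0.05, 1.0)
        assert {n.items for n in neps} == {frozenset({(0, 1)})}

    def test_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            nf = int(rng.integers(1, 7))
            nb = int(rng.integers(2, 5))
            bg = random_item_dataset(rng, nf, nb, int(rng.integers(5, 41)))
            tg = random_item_dataset(rng, nf, nb, int(rng.integers(5, 41)))
            d1 = float(rng.uniform(0.01, 0.2))
            d2 = float(rng.uniform(0.5, 1.0))
            assert ep.mine_neps(bg, tg, d1, d2) == ep.brute_force_neps(bg, tg, d1, d2)


class TestMineBothClasses:
    def test_dominant_positive_item(self):
        # an item in ~88.6% of positives and 0% of negatives must be found
        dp = [(1, 5)] * 31 + [(0, 5)] * 4
        dn = [(2, 5)] * 100
        ep_pos, ep_neg = ep.mine_both_classes(dp, dn, 0.1, 0.7)
        assert frozenset({(0, 1)}) in {n.items for n in ep_pos}

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        dp = random_item_dataset(rng, 3, 3, 20)
        dn = random_item_dataset(rng, 3, 3, 20)
        a, b = ep.mine_both_classes(dp, dn, 0.1, 0.7)
        b2, a2 = ep.mine_both_classes(dn, dp, 0.1, 0.7)
        assert a == a2 and b == b2

    def test_disjoint_classes_both_sides_nonempty(self):
        dp = [(0, 0)] * 10
        dn = [(1, 1)] * 10
        ep_pos, ep_neg = ep.mine_both_classes(dp, dn, 0.1, 0.7)
        assert ep_pos and ep_neg


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.3), st.floats(0.01, 0.3))
def test_constraint_region_monotone_in_thresholds(seed, d1_lo, d1_gap):
    """Raising delta1 (or lowering delta2) never shrinks the set of itemsets
    satisfying the two support conditions, checked before minimality."""
    rng = np.random.default_rng(seed)
    bg = random_item_dataset(rng, 3, 3, 15)
    tg = random_item_dataset(rng, 3, 3, 15)
    d1a, d1b = d1_lo, d1_lo + d1_gap
    d2 = 0.6

    def region(d1):
        out = set()
        feats = sorted({f for row in tg for f in range(len(row))})
        choices = [[None] + sorted({row[f] for row in tg}) for f in feats]
        for combo in itertools.product(*choices):
            items = frozenset((f, b) for f, b in zip(feats, combo) if b is not None)
            if not items:
                continue
            if (ep.support(items, bg) <= d1 + 1e-12
                    and ep.support(items, tg) >= d2 - 1e-12):
                out.add(items)
        return out

    assert region(d1a) <= region(d1b)
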
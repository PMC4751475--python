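"""Mining of minimal noise-tolerant emerging patterns (NEPs).

An *item* is a (feature index, bin index) pair; an *itemset* holds at
most one item per feature.  Given a background class D1 and a target
class D2 of discretized item vectors and thresholds 0 < delta1 <
delta2 <= 1, a noise-tolerant emerging pattern from D1 to D2 is an
itemset X with

1. support_D1(X) <= delta1   (rare in the background),
2. support_D2(X) >= delta2   (frequent in the target),

such that no proper subset of X satisfies condition 1.  The support of
an itemset in a dataset is the fraction of its vectors containing
every item of the itemset (the empty itemset has support 1).

``mine_neps`` is a depth-first search over a frequency-pruned item
lattice with tidset intersection; ``brute_force_neps`` enumerates the
whole itemset lattice and applies the definition literally, serving as
an independent oracle on small instances.

Because support is anti-monotone, condition 1 for *some* proper subset
of X is equivalent to condition 1 for some immediate (|X|-1)-subset;
the miner exploits this for its minimality filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

__all__ = ["NEP", "support", "mine_neps", "brute_force_neps", "mine_both_classes"]

Item = tuple[int, int]  # (feature index, bin index)


@dataclass(frozen=True)
class NEP:
    """A minimal noise-tolerant emerging pattern with its two supports."""

    items: frozenset[Item]
    support_target: float
    support_background: float

    def matches(self, item_vector) -> bool:
        """True when every item of the pattern occurs in ``item_vector``."""
        return all(item_vector[f] == b for f, b in self.items)

    def sorted_items(self) -> list[Item]:
        return sorted(self.items)


def support(itemset, dataset) -> float:
    """Occurrence frequency of ``itemset`` in ``dataset``.

    ``dataset`` is a nonempty list of item vectors (per-feature bin
    tuples).  The empty itemset is contained in every vector.
    """
    if not dataset:
        raise ValueError("support is undefined on an empty dataset")
    items = list(itemset)
    hits = sum(1 for row in dataset if all(row[f] == b for f, b in items))
    return hits / len(dataset)


def _check_thresholds(delta1: float, delta2: float) -> None:
    if not (0 < delta1 < delta2 <= 1):
        raise ValueError(
            f"thresholds must satisfy 0 < delta1 < delta2 <= 1, got {delta1}, {delta2}")


def _item_tidsets(dataset) -> dict[Item, set[int]]:
    tids: dict[Item, set[int]] = {}
    for t, row in enumerate(dataset):
        for f, b in enumerate(row):
            tids.setdefault((f, int(b)), set()).add(t)
    return tids


def mine_neps(background, target, delta1: float, delta2: float) -> set[NEP]:
    """All minimal NEPs from ``background`` (D1) to ``target`` (D2).

    Depth-first search over items ordered by (feature, bin), pruning
    branches whose target support drops below ``delta2`` (anti-monotone)
    and stopping extension once condition 1 holds (any extension would
    violate minimality).  Candidates are post-filtered by checking
    condition 1 on every immediate subset.
    """
    _check_thresholds(delta1, delta2)
    if not background or not target:
        raise ValueError("both classes must be nonempty")
    n1, n2 = len(background), len(target)
    t_tids = _item_tidsets(target)
    b_tids = _item_tidsets(background)
    # items must occur in >= delta2 fraction of targets to be extendable
    min_t = delta2 * n2 - 1e-12
    items = sorted(i for i, tids in t_tids.items() if len(tids) >= min_t)
    empty: set[int] = set()

    candidates: list[tuple[tuple[Item, ...], float, float]] = []

    def dfs(prefix: tuple[Item, ...], tset: set[int], bset: set[int], start: int):
        used_features = {f for f, _ in prefix}
        for idx in range(start, len(items)):
            item = items[idx]
            if item[0] in used_features:
                continue
            new_t = tset & t_tids[item] if prefix else t_tids[item]
            if len(new_t) < min_t:
                continue
            new_b = (bset & b_tids.get(item, empty)) if prefix \
                else b_tids.get(item, set())
            new_prefix = prefix + (item,)
            if len(new_b) <= delta1 * n1 + 1e-12:
                candidates.append((new_prefix, len(new_t) / n2, len(new_b) / n1))
            else:
                dfs(new_prefix, new_t, new_b, idx + 1)

    dfs((), set(range(n2)), set(range(n1)), 0)

    # minimality on condition 1: no immediate subset may be delta1-rare
    result: set[NEP] = set()
    for its, s2, s1 in candidates:
        if len(its) > 1:
            minimal = all(
                support([x for x in its if x != drop], background) > delta1 + 1e-12
                for drop in its)
            if not minimal:
                continue
        result.add(NEP(frozenset(its), s2, s1))
    return result


def brute_force_neps(background, target, delta1: float, delta2: float) -> set[NEP]:
    """Literal enumeration oracle for :func:`mine_neps` (test-size inputs only).

    Enumerates every itemset over items occurring in the target class
    (at most one item per feature) and applies the NEP definition,
    checking minimality against all proper subsets.
    """
    _check_thresholds(delta1, delta2)
    if not background or not target:
        raise ValueError("both classes must be nonempty")
    universe: dict[int, set[int]] = {}
    for row in target:
        for f, b in enumerate(row):
            universe.setdefault(f, set()).add(int(b))
    n_items = sum(len(v) for v in universe.values())
    if n_items > 26:
        raise ValueError(
            f"{n_items} items: the brute-force oracle is for small test instances")

    features = sorted(universe)
    choices = [[None] + sorted(universe[f]) for f in features]
    sup1_cache: dict[frozenset, float] = {frozenset(): 1.0}

    def sup1(itemset: frozenset) -> float:
        if itemset not in sup1_cache:
            sup1_cache[itemset] = support(itemset, background)
        return sup1_cache[itemset]

    result: set[NEP] = set()
    for combo in itertools.product(*choices):
        itemset = frozenset((f, b) for f, b in zip(features, combo) if b is not None)
        if not itemset:
            continue
        s1 = sup1(itemset)
        if s1 > delta1 + 1e-12:
            continue
        s2 = support(itemset, target)
        if s2 < delta2 - 1e-12:
            continue
        minimal = True
        for k in range(len(itemset)):
            for sub in itertools.combinations(itemset, k):
                if sup1(frozenset(sub)) <= delta1 + 1e-12:
                    minimal = False
                    break
            if not minimal:
                break
        if minimal:
            result.add(NEP(itemset, s2, s1))
    return result


def mine_both_classes(dp, dn, delta1: float, delta2: float) -> tuple[set[NEP], set[NEP]]:
    """Mine EP(Dp) (contrasting against Dn) and EP(Dn) (against Dp)."""
    ep_pos = mine_neps(background=dn, target=dp, delta1=delta1, delta2=delta2)
    ep_neg = mine_neps(background=dp, target=dn, delta1=delta1, delta2=delta2)
    return ep_pos, ep_neg
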
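"""Seed-and-grow discovery of candidate complexes.

Starting from a seed protein, the cluster C repeatedly considers the
external neighbor v with the most edges into C (ties broken by
lexicographic ID) and accepts C ∪ {v} only when the clustering score
does not drop, f(C ∪ {v}) >= f(C), and the average degree strictly
rises, avedeg(C ∪ {v}) > avedeg(C).  Growth stops at the first
rejection or when the neighborhood is empty; the grown cluster is kept
only if f(C) > 1/2 and it has at least ``min_size`` members.

Seeds are scheduled in descending network degree among proteins not
yet covered by any accepted complex; every tried seed is marked
visited so the scan terminates even when no complex is found.  Highly
overlapping predictions (overlap score ω >= threshold) are merged into
their union afterwards, and merged unions are re-scored — a union that
no longer satisfies f > 1/2 is discarded, since that is the necessary
condition for calling a subgraph a complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .catalog import ComplexCatalog
from .graph import InteractionNetwork, avedeg, edge_count_to, neighbors
from .scoring import ContrastModel

log = logging.getLogger(__name__)

__all__ = [
    "SearchParams", "PredictionResult",
    "grow_from_seed", "detect_complexes", "overlap_score", "merge_overlapping",
]

F_THRESHOLD = 0.5  # a predicted complex must satisfy f > 1/2


@dataclass(frozen=True)
class SearchParams:
    """Tunables of the search; f_threshold is fixed by the method."""

    min_size: int = 3
    merge_threshold: float = 0.8
    f_threshold: float = F_THRESHOLD
    best_of_k: int = 1   # >1 enables fallback to next-best neighbors

    def __post_init__(self):
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if not (0 < self.merge_threshold <= 1):
            raise ValueError("merge_threshold must be in (0, 1]")
        if self.best_of_k < 1:
            raise ValueError("best_of_k must be >= 1")


@dataclass
class PredictionResult:
    """Predicted complexes with scores and the per-seed growth trace."""

    catalog: ComplexCatalog
    trace: list[dict] = field(default_factory=list)


def grow_from_seed(network: InteractionNetwork, model: ContrastModel,
                   seed: str, min_size: int = 3,
                   attributes: dict[str, dict] | None = None,
                   best_of_k: int = 1,
                   trace: list | None = None) -> frozenset[str] | None:
    """Grow a cluster from ``seed``; return it if it qualifies as a complex.

    Only the ``best_of_k`` external neighbors with the most edges into
    the cluster are tested per iteration (default 1: the literal
    single-candidate rule); the first acceptable one is taken and a
    full rejection ends growth.
    """
    if not network.has_node(seed):
        raise KeyError(f"seed {seed!r} absent from network")
    members = frozenset([seed])
    f = model.score_subgraph(network, members, attributes)
    ad = avedeg(network, members)
    steps = [{"added": seed, "f": f, "avedeg": ad}]
    while True:
        nb = neighbors(network, members)
        if not nb:
            break
        ranked = sorted(nb, key=lambda v: (-edge_count_to(network, v, members), v))
        accepted = False
        for v in ranked[:best_of_k]:
            cand = members | {v}
            f_new = model.score_subgraph(network, cand, attributes)
            ad_new = avedeg(network, cand)
            if f_new >= f and ad_new > ad:
                members, f, ad = cand, f_new, ad_new
                steps.append({"added": v, "f": f, "avedeg": ad})
                accepted = True
                break
        if not accepted:
            break
    ok = f > F_THRESHOLD and len(members) >= min_size
    if trace is not None:
        trace.append({"seed": seed, "steps": steps, "emitted": ok,
                      "final_f": f, "size": len(members)})
    return members if ok else None


def detect_complexes(network: InteractionNetwork, model: ContrastModel,
                     params: SearchParams = SearchParams(),
                     attributes: dict[str, dict] | None = None,
                     keep_trace: bool = False) -> PredictionResult:
    """Run the full seed schedule, then merge overlapping predictions."""
    order = sorted(network.nodes, key=lambda v: (-network.degree(v), v))
    covered: set[str] = set()
    visited: set[str] = set()
    found: list[frozenset[str]] = []
    scores: dict[frozenset[str], float] = {}
    trace: list[dict] | None = [] if keep_trace else None
    for seed in order:
        if seed in covered or seed in visited:
            continue
        visited.add(seed)
        cluster = grow_from_seed(network, model, seed, min_size=params.min_size,
                                 attributes=attributes,
                                 best_of_k=params.best_of_k, trace=trace)
        if cluster is None:
            continue
        covered |= cluster
        if cluster not in scores:
            found.append(cluster)
            scores[cluster] = model.score_subgraph(network, cluster, attributes)
    merged = merge_overlapping(
        ComplexCatalog(found, scores=[scores[c] for c in found]),
        params.merge_threshold)
    final_sets, final_scores = [], []
    for members in merged:
        f = model.score_subgraph(network, members, attributes)
        if f > F_THRESHOLD:
            final_sets.append(members)
            final_scores.append(f)
        else:
            log.info("dropping merged cluster of size %d with f=%.3f <= 1/2",
                     len(members), f)
    return PredictionResult(ComplexCatalog(final_sets, scores=final_scores),
                            trace=trace or [])


def overlap_score(a, b) -> float:
    """ω(a, b) = |a ∩ b|² / (|a| · |b|): 1 iff identical, 0 iff disjoint."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap score is undefined for empty sets")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def merge_overlapping(catalog: ComplexCatalog, threshold: float) -> ComplexCatalog:
    """Union-merge pairs with ω >= threshold, highest ω first, to a fixpoint.

    ω is recomputed after every merge; ties are broken by the sorted
    member lists so the result is deterministic.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    sets = [frozenset(c) for c in catalog]
    # drop exact duplicates up front (a duplicate has omega = 1)
    uniq: list[frozenset[str]] = []
    for s in sets:
        if s not in uniq:
            uniq.append(s)
    sets = uniq
    while True:
        best = None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                w = overlap_score(sets[i], sets[j])
                if w < threshold:
                    continue
                key = (-w, sorted(sets[i]), sorted(sets[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        union = sets[i] | sets[j]
        sets = [s for k, s in enumerate(sets) if k not in (i, j)]
        if union not in sets:
            sets.append(union)
    return ComplexCatalog(sets)
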
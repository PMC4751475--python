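"""Construction of the positive and negative training classes.

The positive class Dp holds the feature vectors of known complexes
mapped onto the network: each catalogued complex is intersected with
the network's node set, complexes left with fewer than three members
are dropped (singletons and pairs carry no subgraph structure), and
exact duplicate member sets are removed.

The negative class Dn holds random subgraphs: node sets drawn
uniformly from the network, 20 per positive instance by default, with
sizes resampled from the empirical positive size list so the negative
size distribution reproduces the positives' (power-law-like) size
distribution by construction.  A sampled set identical to any positive
member set is rejected and redrawn.  An optional connected-negatives
mode grows each random set by a random walk instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .catalog import ComplexCatalog
from .features import extract_features
from .graph import InteractionNetwork

log = logging.getLogger(__name__)

__all__ = [
    "TrainingData",
    "build_positive_instances",
    "sample_negative_subgraphs",
    "assemble_training_data",
]

DEFAULT_NEGATIVE_RATIO = 20
MIN_COMPLEX_SIZE = 3


@dataclass
class TrainingData:
    """Feature matrices of both classes plus full sampling provenance."""

    positive_vectors: np.ndarray          # |Dp| x 22
    negative_vectors: np.ndarray          # |Dn| x 22
    positive_members: list[frozenset[str]]
    negative_members: list[frozenset[str]]
    rng_seed: int


def build_positive_instances(network: InteractionNetwork,
                             catalog: ComplexCatalog) -> list[frozenset[str]]:
    """Map catalogued complexes onto the network.

    Members absent from the network are discarded; complexes with fewer
    than three surviving members are dropped, and exact duplicates keep
    their first occurrence.
    """
    nodes = network.nodes
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    n_small = n_dup = 0
    for members in catalog:
        mapped = frozenset(members & nodes)
        if len(mapped) < MIN_COMPLEX_SIZE:
            n_small += 1
            continue
        if mapped in seen:
            n_dup += 1
            continue
        seen.add(mapped)
        out.append(mapped)
    if n_small or n_dup:
        log.info("build_positive_instances: dropped %d undersized, %d duplicate "
                 "complexes; kept %d", n_small, n_dup, len(out))
    return out


def _random_walk_set(network: InteractionNetwork, nodes: list[str],
                     size: int, rng: np.random.Generator) -> frozenset[str]:
    """Grow a connected node set of ``size`` by a neighborhood walk."""
    g = network.graph
    for _ in range(50):
        current = {nodes[rng.integers(len(nodes))]}
        frontier = set(g.adj[next(iter(current))])
        while len(current) < size and frontier:
            v = sorted(frontier)[rng.integers(len(frontier))]
            current.add(v)
            frontier |= set(g.adj[v])
            frontier -= current
        if len(current) == size:
            return frozenset(current)
    # network too fragmented around sampled starts; fall back to uniform
    idx = rng.choice(len(nodes), size=size, replace=False)
    return frozenset(nodes[i] for i in idx)


def sample_negative_subgraphs(network: InteractionNetwork,
                              positive_sizes: list[int],
                              ratio: int = DEFAULT_NEGATIVE_RATIO,
                              rng: np.random.Generator | None = None,
                              forbidden: set[frozenset[str]] | None = None,
                              connected: bool = False) -> list[frozenset[str]]:
    """Draw ``ratio * len(positive_sizes)`` random node sets.

    Each set's size is drawn uniformly from the empirical
    ``positive_sizes`` list; members are uniform without replacement
    over network nodes (or grown by random walk when ``connected``).
    Sets equal to any ``forbidden`` member set are rejected and redrawn.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not positive_sizes:
        raise ValueError("positive size list is empty")
    nodes = sorted(network.nodes)
    if max(positive_sizes) > len(nodes):
        raise ValueError("requested subgraph size exceeds network size")
    forbidden = forbidden or set()
    out: list[frozenset[str]] = []
    n_total = ratio * len(positive_sizes)
    while len(out) < n_total:
        size = int(positive_sizes[rng.integers(len(positive_sizes))])
        if connected:
            members = _random_walk_set(network, nodes, size, rng)
        else:
            idx = rng.choice(len(nodes), size=size, replace=False)
            members = frozenset(nodes[i] for i in idx)
        if members in forbidden:
            continue
        out.append(members)
    return out


def assemble_training_data(network: InteractionNetwork,
                           catalog: ComplexCatalog,
                           attributes: dict[str, dict] | None = None,
                           ratio: int = DEFAULT_NEGATIVE_RATIO,
                           rng_seed: int = 0,
                           connected_negatives: bool = False) -> TrainingData:
    """Build Dp and Dn feature matrices with provenance."""
    positives = build_positive_instances(network, catalog)
    if len(positives) < 2:
        raise ValueError("insufficient positives to learn contrasts "
                         f"({len(positives)} < 2 usable complexes)")
    rng = np.random.default_rng(rng_seed)
    sizes = [len(p) for p in positives]
    negatives = sample_negative_subgraphs(
        network, sizes, ratio=ratio, rng=rng,
        forbidden=set(positives), connected=connected_negatives)
    pos_mat = np.array([extract_features(network, p, attributes) for p in positives])
    neg_mat = np.array([extract_features(network, q, attributes) for q in negatives])
    return TrainingData(positive_vectors=pos_mat, negative_vectors=neg_mat,
                        positive_members=positives, negative_members=negatives,
                        rng_seed=rng_seed)
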
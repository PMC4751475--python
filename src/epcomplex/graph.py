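"""Core graph primitives for protein–protein interaction (PPI) networks.

A PPI network is an undirected simple graph whose nodes are protein
identifiers.  Candidate and reference complexes are node sets interpreted
as induced subgraphs.  This module provides the handful of subgraph
statistics the detection algorithm is built on: average degree, edge
density, the external neighborhood, and per-node edge counts into a
cluster.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "InteractionNetwork",
    "avedeg",
    "density",
    "neighbors",
    "edge_count_to",
]


class InteractionNetwork:
    """An undirected simple PPI graph with optional node attributes.

    Parameters
    ----------
    graph : networkx.Graph, optional
        Underlying simple graph.  Self-loops are rejected.
    attributes : mapping, optional
        Per-protein attributes: ``{protein_id: {"length": int,
        "weight": float}}`` where *length* is the sequence length in
        residues and *weight* the molecular mass.  ``weight`` may be
        ``None`` when unknown.

    Edge weights (if any) are stored on the graph but are not used by the
    detection algorithm, which is purely topology- and attribute-based.
    """

    def __init__(self, graph: nx.Graph | None = None,
                 attributes: Mapping[str, dict] | None = None):
        g = nx.Graph() if graph is None else graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")
        self.graph = g
        self.attributes = dict(attributes) if attributes else None

    # -- basic queries -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, v: str) -> int:
        return self.graph.degree[v]

    def has_node(self, v: str) -> bool:
        return self.graph.has_node(v)

    def subgraph(self, members: Iterable[str]) -> nx.Graph:
        """Induced subgraph on ``members`` (view, do not mutate)."""
        return self.graph.subgraph(members)

    def __contains__(self, v: str) -> bool:
        return self.graph.has_node(v)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"InteractionNetwork(n_nodes={self.n_nodes}, "
                f"n_edges={self.n_edges}, "
                f"attributes={'yes' if self.attributes else 'no'})")


def _check_members(network: InteractionNetwork, members: Iterable[str]) -> frozenset:
    ms = frozenset(members)
    if not ms:
        raise ValueError("cluster must be nonempty")
    missing = [v for v in ms if not network.has_node(v)]
    if missing:
        raise KeyError(f"cluster members absent from network: {sorted(missing)[:5]}")
    return ms


def avedeg(network: InteractionNetwork, members: Iterable[str]) -> float:
    """Average degree 2|Ec|/|Vc| of the induced subgraph.

    A singleton cluster has average degree 0.
    """
    ms = _check_members(network, members)
    ec = network.subgraph(ms).number_of_edges()
    return 2.0 * ec / len(ms)


def density(network: InteractionNetwork, members: Iterable[str]) -> float:
    """Edge density 2|Ec|/(|Vc|(|Vc|-1)); 0 for a singleton by convention."""
    ms = _check_members(network, members)
    n = len(ms)
    if n <= 1:
        return 0.0
    ec = network.subgraph(ms).number_of_edges()
    return 2.0 * ec / (n * (n - 1))


def neighbors(network: InteractionNetwork, members: Iterable[str]) -> set[str]:
    """External neighborhood N(C): nodes outside C adjacent to >=1 member."""
    ms = _check_members(network, members)
    out: set[str] = set()
    g = network.graph
    for v in ms:
        out.update(g.adj[v])
    return out - ms


def edge_count_to(network: InteractionNetwork, v: str, members: Iterable[str]) -> int:
    """Number of edges connecting external node ``v`` to cluster members."""
    ms = frozenset(members)
    if v in ms:
        raise ValueError(f"node {v!r} is a cluster member")
    if not network.has_node(v):
        raise KeyError(f"node {v!r} absent from network")
    adj = network.graph.adj[v]
    return sum(1 for u in ms if u in adj)
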
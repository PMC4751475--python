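"""Readers and writers for the three flat-file input formats.

* Edge list: whitespace/tab-separated, two protein IDs per line with an
  optional numeric weight in a third column; ``#`` starts a comment line.
  Self-interactions and duplicate (or reversed-duplicate) edges are
  dropped on read.
* Complex catalogue: one complex per line, whitespace-separated protein
  IDs (the MIPS/SGD flat-file convention).
* Attribute table: header-less TSV ``id  length  [weight]`` giving the
  sequence length (residues) and optionally the molecular mass.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .catalog import ComplexCatalog
from .graph import InteractionNetwork

log = logging.getLogger(__name__)

__all__ = [
    "read_network", "read_complexes", "read_attributes",
    "write_network", "write_complexes", "write_scores", "write_attributes",
]


def read_network(path: str | Path) -> InteractionNetwork:
    """Parse a tab/whitespace-separated edge list into a simple graph.

    Self-loops are dropped (a node survives only if it appears in some
    other edge); duplicate and reversed-duplicate edges collapse to one,
    keeping the first weight seen.  Counts of dropped records are logged.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(tokens)}")
            a, b = tokens[0], tokens[1]
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            weight = None
            if len(tokens) >= 3:
                try:
                    weight = float(tokens[2])
                except ValueError:
                    weight = None
            if weight is not None:
                g.add_edge(a, b, weight=weight)
            else:
                g.add_edge(a, b)
    if n_self or n_dup:
        log.info("read_network(%s): dropped %d self-interactions, %d duplicate edges",
                 path, n_self, n_dup)
    return InteractionNetwork(g)


def read_complexes(path: str | Path) -> ComplexCatalog:
    """Read a one-complex-per-line catalogue.

    Duplicate IDs within a line are removed; empty lines are skipped.
    Identical lines are kept as distinct entries — deduplication of the
    training set is done downstream, not by the reader.
    """
    complexes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            complexes.append(frozenset(line.split()))
    return ComplexCatalog(complexes)


def read_attributes(path: str | Path) -> dict[str, dict]:
    """Read a header-less TSV of per-protein attributes.

    Columns: protein ID, sequence length (positive integer, residues),
    optional molecular weight (positive real).  Duplicate IDs and
    non-positive lengths are errors.
    """
    path = Path(path)
    attrs: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected id and length")
            pid = tokens[0]
            if pid in attrs:
                raise ValueError(f"{path}:{lineno}: duplicate protein ID {pid!r}")
            try:
                length = int(tokens[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric length") from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: length must be positive")
            weight = None
            if len(tokens) >= 3:
                try:
                    weight = float(tokens[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric weight") from exc
                if weight <= 0:
                    raise ValueError(f"{path}:{lineno}: weight must be positive")
            attrs[pid] = {"length": length, "weight": weight}
    return attrs


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    """Write an edge list, sorted for reproducible output."""
    with open(path, "w") as fh:
        for a, b, data in sorted(network.graph.edges(data=True),
                                 key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((a, b))
            if "weight" in data:
                fh.write(f"{a}\t{b}\t{data['weight']:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    """Write one complex per line (tab-separated, members sorted)."""
    with open(path, "w") as fh:
        for members in catalog:
            fh.write("\t".join(sorted(members)) + "\n")


def write_scores(catalog: ComplexCatalog, path: str | Path) -> None:
    """Write the per-complex clustering scores as a two-column TSV."""
    if catalog.scores is None:
        raise ValueError("catalog carries no scores")
    with open(path, "w") as fh:
        for members, score in zip(catalog, catalog.scores):
            fh.write(f"{','.join(sorted(members))}\t{score:.6f}\n")


def write_attributes(attrs: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(attrs):
            rec = attrs[pid]
            if rec.get("weight") is not None:
                fh.write(f"{pid}\t{rec['length']}\t{rec['weight']:.4f}\n")
            else:
                fh.write(f"{pid}\t{rec['length']}\n")
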
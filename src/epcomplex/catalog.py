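"""Container for ordered collections of protein complexes."""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

__all__ = ["ComplexCatalog"]


class ComplexCatalog:
    """An ordered list of complexes, each a nonempty frozenset of protein IDs.

    Optionally carries a parallel list of names and of per-complex scores
    (e.g. the clustering score of a prediction).
    """

    def __init__(self, complexes: Iterable[Iterable[str]],
                 names: Sequence[str] | None = None,
                 scores: Sequence[float] | None = None):
        self.complexes: list[frozenset[str]] = [frozenset(c) for c in complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("catalog may not contain an empty complex")
        if names is not None and len(names) != len(self.complexes):
            raise ValueError("names length mismatch")
        if scores is not None and len(scores) != len(self.complexes):
            raise ValueError("scores length mismatch")
        self.names = list(names) if names is not None else None
        self.scores = list(scores) if scores is not None else None

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def __eq__(self, other) -> bool:
        return (isinstance(other, ComplexCatalog)
                and self.complexes == other.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return list(self.complexes)

    def __repr__(self) -> str:  # pragma: no cover
        sizes = [len(c) for c in self.complexes]
        return f"ComplexCatalog(n={len(sizes)}, sizes={sorted(sizes)[:10]}...)"
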
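"""EP-based scoring of candidate subgraphs and the trained contrast model.

A subgraph G is scored against the mined pattern sets of the two
classes.  The aggregate score of G for a class is the sum, over the
class's NEPs contained in Ins(G), of the pattern's target-class
support.  Because the two classes can yield very different numbers of
patterns, each aggregate is normalized by a per-class *base score*:
the median aggregate score of the class's own training instances.  The
clustering score combines the two normalized scores as

    f(G) = np / (np + nn),     f = 0 when np = nn = 0,

so f > 1/2 exactly when the positive normalized score exceeds the
negative one, and f = 1 exactly when G matches no negative-class
pattern at all (nn = 0, np > 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import (BinningScheme, FEATURE_NAMES, discretize, extract_features,
                       fit_binning)
from .graph import InteractionNetwork
from .mining import NEP, mine_both_classes

log = logging.getLogger(__name__)

__all__ = [
    "aggregate_score", "base_score", "normalized_score", "clustering_score",
    "ContrastModel", "train",
]

SCHEMA_VERSION = 1
FEATURE_REGISTRY_VERSION = "topology-attr-22/v1"


def aggregate_score(item_vector, eps) -> float:
    """Sum of target-class supports of the NEPs contained in ``item_vector``."""
    return float(sum(e.support_target for e in eps if e.matches(item_vector)))


def base_score(eps, class_vectors) -> float:
    """Median aggregate score of a class over its own training vectors.

    Guards against a zero base (which would make normalization
    undefined): if the median is 0 the smallest strictly positive
    per-instance score is used, and if every score is 0 the base
    falls back to 1.
    """
    if len(class_vectors) == 0:
        raise ValueError("base score is undefined on an empty class")
    scores = np.array([aggregate_score(v, eps) for v in class_vectors])
    med = float(np.median(scores))
    if med > 0:
        return med
    positive = scores[scores > 0]
    if positive.size:
        fallback = float(positive.min())
        log.warning("base_score: median is 0, falling back to smallest "
                    "positive score %.4f", fallback)
        return fallback
    log.warning("base_score: all per-instance scores are 0, falling back to 1")
    return 1.0


def normalized_score(item_vector, eps, base: float) -> float:
    if base <= 0:
        raise ValueError("base score must be strictly positive")
    return aggregate_score(item_vector, eps) / base


def clustering_score(norm_pos: float, norm_neg: float) -> float:
    """f = np/(np+nn); 0 when both normalized scores vanish."""
    if norm_pos == 0 and norm_neg == 0:
        return 0.0
    return norm_pos / (norm_pos + norm_neg)


@dataclass
class ContrastModel:
    """A trained EP model: patterns, binning, base scores and parameters."""

    ep_pos: list[NEP]
    ep_neg: list[NEP]
    binning: BinningScheme
    base_pos: float
    base_neg: float
    delta1: float
    delta2: float
    rng_seed: int = 0
    params: dict = field(default_factory=dict)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    registry_version: str = FEATURE_REGISTRY_VERSION

    def __post_init__(self):
        if self.base_pos <= 0 or self.base_neg <= 0:
            raise ValueError("base scores must be strictly positive")
        # deterministic pattern order for serialization and scoring
        self.ep_pos = sorted(self.ep_pos, key=lambda e: e.sorted_items())
        self.ep_neg = sorted(self.ep_neg, key=lambda e: e.sorted_items())

    # -- scoring -------------------------------------------------------
    def score_item_vector(self, ins) -> float:
        np_ = normalized_score(ins, self.ep_pos, self.base_pos)
        nn_ = normalized_score(ins, self.ep_neg, self.base_neg)
        return clustering_score(np_, nn_)

    def score_subgraph(self, network: InteractionNetwork, members,
                       attributes: dict[str, dict] | None = None) -> float:
        """Clustering score f of the induced subgraph on ``members``."""
        vec = extract_features(network, members, attributes)
        return self.score_item_vector(discretize(vec, self.binning))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def dump_eps(eps):
            return [{"items": [[self.feature_names[f], b]
                               for f, b in e.sorted_items()],
                     "support_target": e.support_target,
                     "support_background": e.support_background}
                    for e in eps]
        return {
            "schema_version": SCHEMA_VERSION,
            "registry_version": self.registry_version,
            "feature_names": list(self.feature_names),
            "binning": self.binning.to_dict(),
            "ep_pos": dump_eps(self.ep_pos),
            "ep_neg": dump_eps(self.ep_neg),
            "base_pos": self.base_pos,
            "base_neg": self.base_neg,
            "delta1": self.delta1,
            "delta2": self.delta2,
            "rng_seed": self.rng_seed,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContrastModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        names = tuple(d["feature_names"])
        index = {name: i for i, name in enumerate(names)}

        def load_eps(recs):
            return [NEP(frozenset((index[name], int(b)) for name, b in r["items"]),
                        r["support_target"], r["support_background"])
                    for r in recs]
        return cls(ep_pos=load_eps(d["ep_pos"]), ep_neg=load_eps(d["ep_neg"]),
                   binning=BinningScheme.from_dict(d["binning"]),
                   base_pos=d["base_pos"], base_neg=d["base_neg"],
                   delta1=d["delta1"], delta2=d["delta2"],
                   rng_seed=d.get("rng_seed", 0), params=d.get("params", {}),
                   feature_names=names,
                   registry_version=d.get("registry_version",
                                          FEATURE_REGISTRY_VERSION))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "ContrastModel":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"corrupted model file {path}: {exc}") from exc
        return cls.from_dict(d)


def train(network, catalog, attributes=None, *, bins: int = 10,
          delta1: float = 0.1, delta2: float = 0.7, neg_ratio: int = 20,
          rng_seed: int = 0, connected_negatives: bool = False) -> ContrastModel:
    """Train a contrast model (thin wrapper over ComplexDetector.fit)."""
    from .estimator import ComplexDetector
    det = ComplexDetector(bins=bins, delta1=delta1, delta2=delta2,
                          neg_ratio=neg_ratio, random_state=rng_seed,
                          connected_negatives=connected_negatives)
    det.fit(network, catalog, attributes=attributes)
    return det.model_
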
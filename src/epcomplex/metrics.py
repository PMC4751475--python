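"""Quality measures for predicted complex sets.

Given a reference set S and a prediction set P, complexes are matched
by the overlap score ω(s, p) = |s ∩ p|²/(|s||p|) at threshold 0.25.
The suite comprises

* precision |Sp|/|P|, recall (Frac) |St|/|S| and their harmonic mean F1,
  where St (Sp) are the reference (predicted) complexes matched by the
  other side at ω >= 0.25;
* the clustering-wise sensitivity Sen, positive predictive value PPV
  and geometric accuracy Acc = sqrt(Sen · PPV), computed from the
  intersection-count matrix T with T_ij = |s_i ∩ p_j|;
* the maximum matching ratio MMR: the total ω-weight of a maximum-
  weight one-to-one matching between S and P (edges wherever ω > 0),
  divided by |S|;
* the composite score Frac + Acc + MMR.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .catalog import ComplexCatalog
from .search import overlap_score

log = logging.getLogger(__name__)

__all__ = [
    "MATCH_THRESHOLD", "EvaluationReport",
    "match_sets", "precision_recall_f1", "geometric_accuracy",
    "maximum_matching_ratio", "evaluate",
]

MATCH_THRESHOLD = 0.25


def _as_sets(catalog) -> list[frozenset[str]]:
    if isinstance(catalog, ComplexCatalog):
        return catalog.member_sets()
    return [frozenset(c) for c in catalog]


@dataclass(frozen=True)
class EvaluationReport:
    """All measures of one S-vs-P comparison; composite = Frac + Acc + MMR."""

    precision: float
    recall: float
    f1: float
    sen: float
    ppv: float
    acc: float
    mmr: float
    composite: float
    n_reference: int
    n_predicted: int
    n_matched_reference: int
    n_matched_predicted: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_tsv(self) -> str:
        """Header line + value line, for aggregation across runs."""
        keys = list(self.__dict__)
        vals = [f"{v:.6f}" if isinstance(v, float) else str(v)
                for v in self.__dict__.values()]
        return "\t".join(keys) + "\n" + "\t".join(vals) + "\n"


def match_sets(S, P, threshold: float = MATCH_THRESHOLD):
    """Reference and predicted complexes matched at ω >= threshold.

    Returns (St, Sp) as lists in catalogue order.  Empty inputs yield
    empty matches with a warning rather than an error.
    """
    S, P = _as_sets(S), _as_sets(P)
    if not S or not P:
        log.warning("match_sets: empty catalogue(s), no matches possible")
        return [], []
    st = [s for s in S if any(overlap_score(s, p) >= threshold for p in P)]
    sp = [p for p in P if any(overlap_score(s, p) >= threshold for s in S)]
    return st, sp


def precision_recall_f1(S, P, threshold: float = MATCH_THRESHOLD):
    S, P = _as_sets(S), _as_sets(P)
    st, sp = match_sets(S, P, threshold)
    precision = len(sp) / len(P) if P else 0.0
    recall = len(st) / len(S) if S else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def _intersection_matrix(S, P) -> np.ndarray:
    return np.array([[len(s & p) for p in P] for s in S], dtype=float)


def geometric_accuracy(S, P):
    """(Sen, PPV, Acc) from the intersection matrix T.

    Sen = Σ_i max_j T_ij / Σ_i |s_i|; PPV = Σ_j max_i T_ij / Σ_ij T_ij.
    Predictions sharing no protein with any reference contribute
    nothing to either PPV sum.  A fully disjoint P yields PPV = Acc = 0.
    """
    S, P = _as_sets(S), _as_sets(P)
    if not S or not P:
        log.warning("geometric_accuracy: empty catalogue(s)")
        return 0.0, 0.0, 0.0
    t = _intersection_matrix(S, P)
    sen = float(t.max(axis=1).sum() / sum(len(s) for s in S))
    total = t.sum()
    if total == 0:
        log.warning("geometric_accuracy: no shared proteins between S and P")
        return sen, 0.0, 0.0
    ppv = float(t.max(axis=0).sum() / total)
    return sen, ppv, math.sqrt(sen * ppv)


def maximum_matching_ratio(S, P) -> float:
    """Maximum-weight one-to-one ω-matching weight divided by |S|.

    The bipartite graph has an edge (s, p) of weight ω(s, p) for every
    pair with ω > 0; the matching is exact (solved as a rectangular
    assignment problem — with nonnegative weights an optimal assignment
    attains the optimal matching weight).
    """
    S, P = _as_sets(S), _as_sets(P)
    if not S or not P:
        return 0.0
    w = np.array([[overlap_score(s, p) for p in P] for s in S])
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum() / len(S))


def evaluate(S, P, threshold: float = MATCH_THRESHOLD) -> EvaluationReport:
    """Compute the full report for prediction P against reference S."""
    S, P = _as_sets(S), _as_sets(P)
    st, sp = match_sets(S, P, threshold)
    precision = len(sp) / len(P) if P else 0.0
    recall = len(st) / len(S) if S else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    sen, ppv, acc = geometric_accuracy(S, P)
    mmr = maximum_matching_ratio(S, P)
    return EvaluationReport(
        precision=precision, recall=recall, f1=f1,
        sen=sen, ppv=ppv, acc=acc, mmr=mmr,
        composite=recall + acc + mmr,
        n_reference=len(S), n_predicted=len(P),
        n_matched_reference=len(st), n_matched_predicted=len(sp))
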
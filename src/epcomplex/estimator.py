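"""The top-level supervised complex detector, scikit-learn style.

``ComplexDetector`` bundles the full pipeline: build the positive and
negative training classes, extract and discretize the 22-feature
vectors, mine noise-tolerant emerging patterns for both classes,
derive base scores — that is ``fit`` — and then run the seed-and-grow
search on a network to ``predict`` complexes.  It follows the familiar
estimator conventions (``get_params``/``set_params``, trailing-
underscore fitted attributes) so it composes with scikit-learn
tooling, although its X is an :class:`~epcomplex.graph.InteractionNetwork`
rather than an array.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .catalog import ComplexCatalog
from .features import discretize, fit_binning
from .graph import InteractionNetwork
from .mining import mine_both_classes
from .scoring import ContrastModel, base_score
from .search import PredictionResult, SearchParams, detect_complexes
from .training import assemble_training_data

log = logging.getLogger(__name__)

__all__ = ["ComplexDetector"]


class ComplexDetector(BaseEstimator):
    """Supervised protein-complex detection via emerging-pattern contrasts.

    Parameters
    ----------
    bins : int, default 10
        Equal-width bins per feature for discretization.
    delta1, delta2 : float, defaults 0.1 and 0.7
        Background-rarity and target-frequency support thresholds of
        the pattern miner; 0 < delta1 < delta2 <= 1.
    neg_ratio : int, default 20
        Random subgraphs sampled per positive training complex.
    min_size : int, default 3
        Minimum size of an emitted complex.
    merge_threshold : float, default 0.8
        Overlap score at or above which two predictions are merged.
    connected_negatives : bool, default False
        Sample negatives as random-walk-connected subgraphs instead of
        uniform node sets.
    best_of_k : int, default 1
        Neighbors tested per growth step (1 = strict best-candidate rule).
    random_state : int, default 0
        Seed for negative sampling; fixes the whole pipeline.

    Attributes
    ----------
    model_ : ContrastModel
        Trained patterns, binning and base scores.
    n_positive_, n_negative_ : int
        Training class sizes |Dp| and |Dn|.
    training_ : TrainingData
        Feature matrices and sampling provenance.
    """

    def __init__(self, bins: int = 10, delta1: float = 0.1, delta2: float = 0.7,
                 neg_ratio: int = 20, min_size: int = 3,
                 merge_threshold: float = 0.8, connected_negatives: bool = False,
                 best_of_k: int = 1, random_state: int = 0):
        self.bins = bins
        self.delta1 = delta1
        self.delta2 = delta2
        self.neg_ratio = neg_ratio
        self.min_size = min_size
        self.merge_threshold = merge_threshold
        self.connected_negatives = connected_negatives
        self.best_of_k = best_of_k
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate(self, network) -> None:
        if not isinstance(network, InteractionNetwork):
            raise TypeError("network must be an InteractionNetwork")
        if not (0 < self.delta1 < self.delta2 <= 1):
            raise ValueError("need 0 < delta1 < delta2 <= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")

    def fit(self, network: InteractionNetwork, complexes: ComplexCatalog,
            attributes: dict[str, dict] | None = None) -> "ComplexDetector":
        """Train the contrast model from a network and a complex catalogue."""
        self._validate(network)
        data = assemble_training_data(
            network, complexes, attributes=attributes, ratio=self.neg_ratio,
            rng_seed=self.random_state,
            connected_negatives=self.connected_negatives)
        pooled = np.vstack([data.positive_vectors, data.negative_vectors])
        binning = fit_binning(pooled, bins=self.bins)
        dp = [discretize(v, binning) for v in data.positive_vectors]
        dn = [discretize(v, binning) for v in data.negative_vectors]
        ep_pos, ep_neg = mine_both_classes(dp, dn, self.delta1, self.delta2)
        if not ep_pos or not ep_neg:
            log.warning("fit: empty pattern set (|EP(Dp)|=%d, |EP(Dn)|=%d); "
                        "the model will score weakly", len(ep_pos), len(ep_neg))
        self.model_ = ContrastModel(
            ep_pos=sorted(ep_pos, key=lambda e: e.sorted_items()),
            ep_neg=sorted(ep_neg, key=lambda e: e.sorted_items()),
            binning=binning,
            base_pos=base_score(ep_pos, dp),
            base_neg=base_score(ep_neg, dn),
            delta1=self.delta1, delta2=self.delta2,
            rng_seed=self.random_state,
            params={"bins": self.bins, "neg_ratio": self.neg_ratio,
                    "n_positive": len(dp), "n_negative": len(dn),
                    "connected_negatives": self.connected_negatives})
        self.training_ = data
        self.n_positive_ = len(dp)
        self.n_negative_ = len(dn)
        return self

    def predict(self, network: InteractionNetwork,
                attributes: dict[str, dict] | None = None,
                keep_trace: bool = False) -> ComplexCatalog:
        """Detect complexes in a network (which may differ from the
        training network, e.g. cross-species application)."""
        return self.predict_result(network, attributes, keep_trace).catalog

    def predict_result(self, network: InteractionNetwork,
                       attributes: dict[str, dict] | None = None,
                       keep_trace: bool = False) -> PredictionResult:
        """Like :meth:`predict` but returns scores and the growth trace."""
        if not hasattr(self, "model_"):
            raise RuntimeError("detector is not fitted; call fit() first")
        params = SearchParams(min_size=self.min_size,
                              merge_threshold=self.merge_threshold,
                              best_of_k=self.best_of_k)
        return detect_complexes(network, self.model_, params,
                                attributes=attributes, keep_trace=keep_trace)

    def fit_predict(self, network, complexes, attributes=None) -> ComplexCatalog:
        return self.fit(network, complexes, attributes).predict(network, attributes)

    def score(self, network: InteractionNetwork, reference: ComplexCatalog,
              attributes: dict[str, dict] | None = None) -> float:
        """Composite score (Frac + Acc + MMR) of predictions vs a reference."""
        from .metrics import evaluate
        pred = self.predict(network, attributes)
        return evaluate(reference, pred).composite
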
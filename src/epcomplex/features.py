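"""22-dimensional topological/attribute feature vectors for subgraphs.

Every candidate or reference complex is summarised by 22 real-valued
features of its induced subgraph: node size, graph density, and six
groups of statistics — degree, degree correlation, local clustering
coefficient, topological coefficient, the leading eigenvalues of the
adjacency and Laplacian matrices, and protein size/weight statistics
from an optional attribute table.

For supervised contrast mining the continuous features are discretized
into equal-width bins fitted on the pooled training matrix; a
(feature, bin) pair is an *item* and a discretized vector an *item
vector*.

Conventions for degenerate subgraphs
------------------------------------
Singletons have all topology statistics equal to 0.  Per-node degrees
are normalized by |Vc|-1 so every degree statistic lives in [0, 1].
The degree correlation of a node is the mean within-subgraph degree of
its neighbors divided by its own degree (0 for isolated nodes): a
ratio-type quantity that can exceed 1 in star-like subgraphs.  The
topological coefficient of node n is the mean, over partners m sharing
at least one neighbor with n, of |J(n, m)|/deg(n), where J(n, m) is
the shared-neighbor set (plus one if n and m are adjacent); it is 0
for nodes of degree < 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import InteractionNetwork, _check_members

__all__ = [
    "FEATURE_NAMES", "N_FEATURES",
    "extract_features", "BinningScheme", "fit_binning", "discretize",
]

FEATURE_NAMES: tuple[str, ...] = (
    "node_size",
    "graph_density",
    "mean_degree", "max_degree", "var_degree",
    "mean_degree_correlation", "max_degree_correlation", "var_degree_correlation",
    "mean_clustering_coeff", "max_clustering_coeff", "var_clustering_coeff",
    "mean_topological_coeff", "max_topological_coeff", "var_topological_coeff",
    "first_eigenvalue_adjacency",
    "first_eigenvalue_laplacian",
    "mean_length", "max_length", "var_length",
    "mean_weight", "max_weight", "var_weight",
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 22


def _stats(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, max, population variance) of a nonempty array."""
    return float(values.mean()), float(values.max()), float(values.var())


def _topological_coefficients(sub: nx.Graph) -> np.ndarray:
    nodes = list(sub.nodes)
    adj = {v: set(sub.adj[v]) for v in nodes}
    out = np.zeros(len(nodes))
    for i, n in enumerate(nodes):
        deg = len(adj[n])
        if deg < 2:
            continue
        scores = []
        for m in nodes:
            if m == n:
                continue
            shared = len(adj[n] & adj[m])
            if shared == 0:
                continue
            if m in adj[n]:
                shared += 1
            scores.append(shared / deg)
        if scores:
            out[i] = float(np.mean(scores))
    return out


def extract_features(network: InteractionNetwork, members,
                     attributes: dict[str, dict] | None = None) -> np.ndarray:
    """Compute the 22-feature vector of the induced subgraph on ``members``.

    ``attributes`` overrides the network's own attribute table; when
    neither is present the six length/weight statistics are 0.

    Returns a float array of length 22 ordered as ``FEATURE_NAMES``.
    """
    ms = _check_members(network, members)
    if attributes is None:
        attributes = network.attributes
    sub = network.subgraph(ms)
    n = len(ms)
    nodes = list(sub.nodes)
    vec = np.zeros(N_FEATURES)
    vec[0] = n
    if n >= 2:
        m = sub.number_of_edges()
        vec[1] = 2.0 * m / (n * (n - 1))
        degs = np.array([sub.degree[v] for v in nodes], dtype=float)
        vec[2:5] = _stats(degs / (n - 1))
        # degree correlation: mean neighbor degree over own degree, 0 if isolated
        corr = np.zeros(n)
        for i, v in enumerate(nodes):
            if degs[i] > 0:
                corr[i] = np.mean([sub.degree[u] for u in sub.adj[v]]) / degs[i]
        vec[5:8] = _stats(corr)
        cc = np.array([nx.clustering(sub, v) for v in nodes])
        vec[8:11] = _stats(cc)
        vec[11:14] = _stats(_topological_coefficients(sub))
        a = nx.to_numpy_array(sub, nodelist=nodes)
        vec[14] = float(np.linalg.eigvalsh(a)[-1])
        lap = np.diag(a.sum(axis=1)) - a
        vec[15] = float(np.linalg.eigvalsh(lap)[-1])
    if attributes:
        lengths = np.array([attributes[v]["length"]
                            for v in nodes if v in attributes], dtype=float)
        weights = np.array([attributes[v]["weight"]
                            for v in nodes
                            if v in attributes and attributes[v].get("weight") is not None],
                           dtype=float)
        if lengths.size:
            vec[16:19] = _stats(lengths)
        if weights.size:
            vec[19:22] = _stats(weights)
    return vec


@dataclass(frozen=True)
class BinningScheme:
    """Per-feature equal-width binning fitted on a training matrix.

    ``lower``/``upper`` are the observed per-feature ranges; features
    with ``upper == lower`` are degenerate and map every value to bin 0.
    """

    lower: np.ndarray
    upper: np.ndarray
    bins: int = 10

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("bin count must be >= 2")
        if np.any(self.upper < self.lower):
            raise ValueError("upper bound below lower bound")

    @property
    def width(self) -> np.ndarray:
        return (self.upper - self.lower) / self.bins

    def is_degenerate(self) -> np.ndarray:
        return self.upper == self.lower

    def to_dict(self) -> dict:
        return {"lower": self.lower.tolist(),
                "upper": self.upper.tolist(),
                "bins": self.bins}

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(lower=np.asarray(d["lower"], dtype=float),
                   upper=np.asarray(d["upper"], dtype=float),
                   bins=int(d["bins"]))


def fit_binning(matrix, bins: int = 10) -> BinningScheme:
    """Fit per-feature [min, max] ranges over a list of feature vectors."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("feature matrix must be a nonempty 2-D array")
    return BinningScheme(lower=arr.min(axis=0), upper=arr.max(axis=0), bins=bins)


def discretize(vector, scheme: BinningScheme) -> tuple[int, ...]:
    """Map a feature vector to per-feature bin indices.

    A value v maps to floor((v - lo)/width), clipped into [0, bins-1];
    values outside the fitted range clip to the boundary bins, and
    degenerate features always map to bin 0.
    """
    v = np.asarray(vector, dtype=float)
    width = scheme.width
    safe = np.where(width > 0, width, 1.0)
    raw = np.floor((v - scheme.lower) / safe)
    raw = np.where(width > 0, raw, 0.0)
    bins = np.clip(raw, 0, scheme.bins - 1).astype(int)
    return tuple(int(b) for b in bins)
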
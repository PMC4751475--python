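import networkx as nx
import numpy as np
import pytest

import epcomplex as ep


@pytest.fixture
def k4_net():
    return ep.InteractionNetwork(nx.complete_graph(["a", "b", "c", "d"]))


@pytest.fixture
def triangle_plus_tail():
    """Triangle a-b-c with a pendant edge a-d."""
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
    return ep.InteractionNetwork(g)


@pytest.fixture
def path3_net():
    return ep.InteractionNetwork(nx.path_graph(["a", "b", "c"]))


@pytest.fixture(scope="session")
def dense_benchmark():
    """Standard planted benchmark (seed 1) with a fitted detector."""
    net, cat, attrs = ep.generate_benchmark(ep.FixtureSpec(rng_seed=1))
    train, test = ep.split_catalog(cat, 0.5, rng=1)
    det = ep.ComplexDetector(random_state=1).fit(net, train, attributes=attrs)
    return {"network": net, "catalog": cat, "attributes": attrs,
            "train": train, "test": test, "detector": det}


def random_item_dataset(rng: np.random.Generator, n_features: int,
                        n_bins: int, n_rows: int) -> list[tuple[int, ...]]:
    """Random discretized dataset: one bin per feature per row."""
    return [tuple(int(b) for b in rng.integers(0, n_bins, n_features))
            for _ in range(n_rows)]
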
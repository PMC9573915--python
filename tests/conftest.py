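import numpy as np
import pytest

from icarlap import ModelData, edges_to_graph
from icarlap.fixtures import cycle_graph, path_graph


@pytest.fixture
def path3():
    return path_graph(3)


@pytest.fixture
def cycle4():
    return cycle_graph(4)


@pytest.fixture
def path3_data(path3):
    return ModelData([3, 1, 0], [1.0, 1.0, 1.0], np.empty((3, 0)), path3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_graph(rng, n, p=0.4):
    """Erdos-Renyi style labelled graph for property tests."""
    import warnings

    labels = [f"v{i}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.uniform() < p
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated vertices are fine here
        return edges_to_graph(edges, labels)
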
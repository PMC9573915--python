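"""Versioned tiny-instance fixture set used by `validate` and the tests.

Graphs with n <= 5 and small fixed counts, crossed with a grid of parameter
values; brute-force quadrature over the constrained subspace is feasible on
every instance.
"""

from __future__ import annotations

import numpy as np

from .graph import SpatialGraph, edges_to_graph
from .model import ICARParams, ModelData

__all__ = ["oracle_fixture_set", "path_graph", "cycle_graph"]


def path_graph(n: int) -> SpatialGraph:
    labels = [f"v{i}" for i in range(n)]
    return edges_to_graph([(f"v{i}", f"v{i + 1}") for i in range(n - 1)], labels)


def cycle_graph(n: int) -> SpatialGraph:
    labels = [f"v{i}" for i in range(n)]
    edges = [(f"v{i}", f"v{(i + 1) % n}") for i in range(n)]
    return edges_to_graph(edges, labels)


def _instances():
    g2 = path_graph(2)
    g3 = path_graph(3)
    g4c = cycle_graph(4)
    g5 = path_graph(5)
    yield "edge_n2_null", ModelData([0, 0], [1.0, 1.0], np.empty((2, 0)), g2)
    yield "edge_n2_counts", ModelData([3, 1], [2.0, 1.5], np.empty((2, 0)), g2)
    yield "path_n3", ModelData([3, 1, 0], [1.0, 1.0, 1.0], np.empty((3, 0)), g3)
    yield "cycle_n4", ModelData([2, 0, 5, 1], [1.5, 1.0, 2.0, 1.0], np.empty((4, 0)), g4c)
    # larger offsets keep the Laplace error inside the asserted band at the
    # largest tau in the grid (the approximation degrades for tiny counts)
    yield "path_n5", ModelData([1, 4, 0, 2, 3], [5.0, 6.0, 5.0, 5.5, 6.5], np.empty((5, 0)), g5)


_THETA_GRID = [
    ICARParams(beta0=0.0, log_tau=0.0),
    ICARParams(beta0=0.3, log_tau=float(np.log(0.5))),
    ICARParams(beta0=-0.5, log_tau=float(np.log(1.5))),
]


def oracle_fixture_set():
    """Yield (label, data, params) across the instance x theta grid."""
    for label, data in _instances():
        for t, params in enumerate(_THETA_GRID):
            yield f"{label}/theta{t}", data, params
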
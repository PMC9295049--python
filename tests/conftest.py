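import numpy as np
import pytest

from graphmm.graphs import (Graph, build_lattice_graph,
                            enumerate_graph_respecting_partitions, make_edges)


@pytest.fixture(scope="session")
def lattice33() -> Graph:
    return build_lattice_graph((3, 3))


@pytest.fixture(scope="session")
def partitions33(lattice33):
    return enumerate_graph_respecting_partitions(lattice33)


@pytest.fixture(scope="session")
def path3() -> Graph:
    return Graph(n=3, edges=make_edges([(0, 1), (1, 2)]))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
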
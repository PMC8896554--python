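import numpy as np
import pytest

from latentlearn.graphs import (
    build_lattice_graph,
    build_modular_graph,
    random_walk,
    transition_matrix,
)


@pytest.fixture(scope="session")
def modular():
    return build_modular_graph()


@pytest.fixture(scope="session")
def lattice():
    return build_lattice_graph()


@pytest.fixture(scope="session")
def A_mod(modular):
    return transition_matrix(modular)


@pytest.fixture(scope="session")
def A_lat(lattice):
    return transition_matrix(lattice)


@pytest.fixture(scope="session")
def walk_1000(A_mod):
    return random_walk(A_mod, 1000, seed=12345)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
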
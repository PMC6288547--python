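import warnings

import numpy as np
import pytest

from phyloarch import read_newick
from phyloarch.simulate import SimulationConfig, simulate_bd_tree


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star8():
    labs = ",".join(f"s{i}:1" for i in range(8))
    return read_newick(f"({labs});")


@pytest.fixture
def tree27():
    return simulate_bd_tree(SimulationConfig(seed=42))


def random_tree(seed, n, crown_age=None, birth=1.0, death=0.0):
    return simulate_bd_tree(SimulationConfig(seed=seed, n_species=n,
                                             crown_age=crown_age, birth=birth,
                                             death=death))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
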
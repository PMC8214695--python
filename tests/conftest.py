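import numpy as np
import pytest

from islandrad import (GeographyModel, tree_from_newick, simulate_climate)
from islandrad.simulate import default_geography


@pytest.fixture
def geo2():
    """Two always-available areas 100 km apart."""
    return GeographyModel(["A", "B"], np.array([[0.0, 100.0], [100.0, 0.0]]),
                          np.array([np.inf, np.inf]))


@pytest.fixture
def geo4():
    """The four-archipelago system with emergence strata."""
    return default_geography()


@pytest.fixture
def tree2():
    return tree_from_newick("(t1:1.3,t2:1.3);")


@pytest.fixture
def tree3():
    return tree_from_newick("((t1:1,t2:1):1,t3:2);")


@pytest.fixture
def cooling_climate():
    """Deterministic Cenozoic-shaped cooling curve spanning 45 Ma."""
    return simulate_climate(span=45, trend=(12, 1), noise_sd=0.0, seed=7)
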
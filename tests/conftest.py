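import numpy as np
import pytest

from nodevo.codon_model import assign_uniform_classes
from nodevo.data_io import RunConfig, read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fast_config():
    """Single-start optimizer config for speed-sensitive tests."""
    return RunConfig(n_starts=1, seed=0)


@pytest.fixture
def quartet_tree():
    phy = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.1);")
    return assign_uniform_classes(phy)


@pytest.fixture
def octet_tree():
    phy = read_newick(
        "((A:0.1,B:0.15):0.05,(C:0.2,D:0.1):0.05,"
        "((E:0.1,F:0.1):0.1,(G:0.15,H:0.1):0.05):0.05);"
    )
    return assign_uniform_classes(phy)
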
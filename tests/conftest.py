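import numpy as np
import pytest

from phylomi.trees import read_newick_string
from phylomi.simulate import simulate_tree


@pytest.fixture
def balanced3():
    """((A:1,B:1):1,C:2); — ultrametric, depth 2."""
    return read_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree10():
    return simulate_tree(10, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
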
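import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """Two clones, one collective each, two particles: {1,3} and {5,7}.

    Hand computation (grand mean 4): SSA = 16, SS(B/A) = 0, SS(C/B) = 4,
    SST = 20, particle H2 = 0.8, ratio = 1.25.
    """
    from heritsim import NestedPhenotypeTable

    return NestedPhenotypeTable(np.array([[[1.0, 3.0]], [[5.0, 7.0]]]))
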
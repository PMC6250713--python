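import numpy as np
import pytest

from neuromine.homology import blosum62
from neuromine.synth import generate_dataset


@pytest.fixture(scope="session")
def scheme():
    return blosum62()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study: 10 precursors, 40 decoys, 20% divergence."""
    return generate_dataset(n_precursors=10, divergence=0.2, n_decoys=40,
                            seed=5, n_observations=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
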
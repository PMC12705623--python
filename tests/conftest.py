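import numpy as np
import pytest

from herbgat.pipeline import assemble_dataset
from herbgat.synthetic import SynthConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact featurized corpus shared across tests."""
    return generate_synthetic_dataset(SynthConfig(
        n_prescriptions=120, n_herbs=30, n_metabolites=50, n_targets=40,
        positive_fraction=0.4, seed=5))


@pytest.fixture(scope="session")
def small_assembled(small_dataset):
    return assemble_dataset(small_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
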
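import numpy as np
import pytest

from biosig.siamese import SiameseSpec, train
from biosig.store import stack_covariates
from biosig.synthetic import UniverseConfig, generate_universe
from biosig.triplets import sample_triplets, split_molecules

SMALL_TARGET = "A3"


@pytest.fixture(scope="session")
def small_universe():
    """400 molecules, 5 spaces, 32-d signatures, 8 shared latent factors."""
    return generate_universe(
        UniverseConfig(n_molecules=400, n_spaces=5, d=32, h=8, seed=11)
    )


@pytest.fixture(scope="session")
def small_split(small_universe):
    space = small_universe[SMALL_TARGET]
    return split_molecules(space.keys, seed=11)


@pytest.fixture(scope="session")
def small_triplets(small_universe, small_split):
    train_keys, test_keys = small_split
    return sample_triplets(
        small_universe[SMALL_TARGET], 4000, k=10, seed=11,
        train_keys=train_keys, test_keys=test_keys,
    )


@pytest.fixture(scope="session")
def small_model(small_universe, small_triplets):
    return train(
        small_universe, SMALL_TARGET, small_triplets, SiameseSpec(seed=11)
    )


@pytest.fixture(scope="session")
def small_covariates(small_universe):
    return stack_covariates(small_universe, SMALL_TARGET)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
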
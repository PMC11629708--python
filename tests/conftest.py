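import numpy as np
import pytest

from pocketdti import FixtureSpec, generate_dataset
from pocketdti.model import DTIModel, ModelConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_table():
    """8 drugs x 6 proteins, noise-free planted rule."""
    table, ann = generate_dataset(FixtureSpec(n_drugs=8, n_proteins=6, seed=3))
    return table, ann


@pytest.fixture(scope="session")
def small_model():
    """A compact model instance shared by read-only tests."""
    return DTIModel(ModelConfig(h=32, n_heads=2, d_plm=32, seed=7))


@pytest.fixture(scope="session")
def small_cache(small_model, tiny_table):
    cache = small_model.new_cache()
    cache.add_table(tiny_table[0])
    return cache
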
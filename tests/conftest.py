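import numpy as np
import pytest

from mrsdm import MultiRealmConfig, generate_seascape


@pytest.fixture(scope="session")
def small_world():
    """A 30x30 seascape shared by read-only tests."""
    return generate_seascape(30, 30, seed=11)


@pytest.fixture()
def small_config():
    return MultiRealmConfig(mmfd_m=40_000.0, n_pseudo=80, n_sets=2, n_repeats=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
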
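import numpy as np
import pytest

from wgdkit.simulate import SimConfig, simulate_homology_dataset


@pytest.fixture(scope="session")
def small_homology():
    """A 500-family, 3-species simulated homology dataset."""
    return simulate_homology_dataset(SimConfig(seed=0, n_families=500))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
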
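import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def sim20():
    """One 20 dB simulated spectrum shared across tests."""
    from aispls.simulate import simulate_dataset

    return simulate_dataset(20, seed=7)
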
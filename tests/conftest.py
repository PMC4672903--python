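import numpy as np
import pytest

from dualbolus.phantom import make_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default dual-bolus phantom (shared across tests)."""
    return make_phantom(snr=None, seed=7)


@pytest.fixture(scope="session")
def snr30_phantom():
    """Default phantom at baseline SNR 30, the study noise level."""
    return make_phantom(snr=30.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
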
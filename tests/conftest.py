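import numpy as np
import pytest

from vedicnn import phantom_data as pd_


@pytest.fixture(scope="session")
def small_phantoms():
    """Tiny seeded train/test phantom split shared across tests."""
    return pd_.generate_dataset(12, seed=101, size=(32, 32))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
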
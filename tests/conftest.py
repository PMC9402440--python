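import numpy as np
import pytest

from lymphforge import signature_attribution as sa


@pytest.fixture(scope="session")
def catalog():
    """The packaged synthetic signature catalogue (signatures x 96)."""
    return sa.load_signature_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
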
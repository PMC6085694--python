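import numpy as np
import pytest

from emseg import phantom as ph


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A small but fully featured phantom shared across read-only tests."""
    cfg = ph.PhantomConfig(shape=(40, 64, 64), n_mitochondria=5, n_synapses=3,
                           seed=7)
    return ph.generate(cfg)
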
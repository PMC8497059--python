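import numpy as np
import pytest

from mutspec.pool import PoolConfig


@pytest.fixture
def pool_cfg():
    return PoolConfig(n_mutants=38)


@pytest.fixture
def denovo_class_probs():
    """A realistic reporter-gene de novo spectrum (6 subs + 1-bp indels)."""
    return {"A>C": 0.08, "A>G": 0.22, "A>T": 0.10, "C>A": 0.15,
            "C>G": 0.10, "C>T": 0.25, "ins1": 0.05, "del1": 0.05}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
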
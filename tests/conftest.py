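import numpy as np
import pytest

from germsoma import synthetic_data as sd


@pytest.fixture
def genome_100kb():
    return sd.gen_genome(1, 100_000, seed=0)


@pytest.fixture
def genome_2x1mb():
    return sd.gen_genome(2, 1_000_000, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
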
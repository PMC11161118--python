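import numpy as np
import pytest

from spikeprofile import SpikeTrain, compute_isi, standardize_length
from spikeprofile.synthetic import gen_renewal_train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iid_isi_225(rng):
    """An i.i.d. exponential ISI sequence of the standardized length."""
    return rng.exponential(0.1, 225)


@pytest.fixture
def monotone_isi_225():
    """Strictly increasing ISI sequence: a single ordinal pattern."""
    return np.linspace(0.01, 0.5, 225)


@pytest.fixture
def poisson_train():
    return gen_renewal_train(8.0, 1.0, 2000, seed=7)


@pytest.fixture
def standardized_isi(poisson_train):
    return standardize_length(compute_isi(poisson_train), 225)


@pytest.fixture
def periodic_train():
    """Perfectly periodic 5 Hz train (period 0.2 s) lasting 100 s."""
    return SpikeTrain(timestamps=np.arange(0, 100.0001, 0.2))
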
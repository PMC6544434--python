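import numpy as np
import pytest

from xmv1 import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy 60-neuron dataset shared by read-only tests."""
    return synthetic.make_dataset(n_neurons=60, n_repetitions=10, seed=7)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, neuropil-free, gain-free dataset for identities."""
    return synthetic.make_dataset(
        n_neurons=16, n_repetitions=10, noise_sd=0.0, neuropil_amp=0.0,
        trial_gain_cv=0.0, seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
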
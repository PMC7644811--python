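import numpy as np
import pytest

from synlab import synthetic


@pytest.fixture(scope="session")
def noiseless_trial():
    """Rank-4, 30-cycle trial with no envelope noise and no jitter."""
    return synthetic.generate_trial(
        r=4, n_cycles=30, noise_sd=0.0, jitter_sd=0.0, amplitude_cv=0.0, seed=1
    )


@pytest.fixture(scope="session")
def noisy_trial():
    """Rank-4 trial at the generator's default noise and jitter."""
    return synthetic.generate_trial(r=4, n_cycles=30, noise_sd=0.05, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def wrapped_bell(peak, sigma=8.0, n=200):
    """Single-cycle wrapped-Gaussian activation bell (test helper)."""
    t = np.arange(n)
    d = np.abs(t - peak)
    d = np.minimum(d, n - d)
    return np.exp(-0.5 * (d / sigma) ** 2)
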
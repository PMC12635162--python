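import numpy as np
import pytest

from pnms import PhantomSpec, make_phantom_subject


@pytest.fixture(scope="session")
def noiseless_subject():
    """One left-sided phantom with no noise (planted effects exact)."""
    return make_phantom_subject(PhantomSpec(noise_sd=0.0), subject_seed=0, ez_side="left")


@pytest.fixture(scope="session")
def noisy_subject():
    return make_phantom_subject(PhantomSpec(), subject_seed=3, ez_side="right")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
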
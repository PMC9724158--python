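import numpy as np
import pytest

from eggan.phantoms import PhantomSpec, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """48-pixel noiseless-ish phantom spec shared by fast tests."""
    return PhantomSpec(image_size=48, noise_sigma=(20.0, 20.0), seed=11)


@pytest.fixture(scope="session")
def paired_set(small_spec):
    return make_dataset(small_spec, 6, paired=True)
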
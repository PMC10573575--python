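import numpy as np
import pytest

from choroquant.attenuation import compensate_attenuation
from choroquant.surfaces import segment_choroid
from choroquant.synthetic import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Standard desk-scale phantom with speckle noise."""
    return generate_phantom(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomParams(seed=1, speckle_shape=0.0))


@pytest.fixture(scope="session")
def segmented_phantom(phantom):
    """Phantom plus its compensated volume and automatic surfaces."""
    vol, truth = phantom
    comp = compensate_attenuation(vol)
    surf = segment_choroid(vol)
    return vol, truth, comp, surf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
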
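import numpy as np
import pytest

from fracrecon.phantoms import PhantomParams, make_phantom, region_map


@pytest.fixture(scope="session")
def default_phantom():
    """One intact 64-cube phantom shared by read-only tests."""
    params = PhantomParams()
    vol, frags = make_phantom(params)
    return params, vol, frags


@pytest.fixture(scope="session")
def default_region_boxes(default_phantom):
    params, _, _ = default_phantom
    return region_map(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
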
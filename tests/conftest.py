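import numpy as np
import pytest

from strokect.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def stroke_phantom():
    """One deterministic stroke phantom shared across read-only tests."""
    return generate_phantom(PhantomParams(seed=42))


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom(PhantomParams(seed=43, lesion_count_range=(0, 0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
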
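import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_affine():
    return np.eye(4)


@pytest.fixture
def small_volume(rng, identity_affine):
    from datbridge.volume_io import Volume

    return Volume(data=rng.random((6, 6, 6)), affine=identity_affine)
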
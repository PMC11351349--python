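import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dwicycle.synthetic_dwi import AcquisitionSpec, generate_scene, make_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small 32x32 two-domain phantom dataset shared across tests."""
    root = tmp_path_factory.mktemp("tinyds")
    spec = AcquisitionSpec(image_size=(32, 32), seed=11)
    manifest = make_dataset(2, 1, (3, 3), spec, root)
    return root, manifest


@pytest.fixture()
def scene64():
    return generate_scene((64, 64), 2, 0.2, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
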
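import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tumorseg import PhantomSpec, make_phantom, segment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """The canonical test phantom: 8-voxel sphere, 150/90 contrast, sigma 8."""
    spec = PhantomSpec()
    volume, truth, seeds = make_phantom(spec)
    return spec, volume, truth, seeds


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    """One full default-parameter segmentation run, shared across tests."""
    _, volume, truth, seeds = default_phantom
    return segment(volume, seeds)


@pytest.fixture()
def step_edge_volume():
    """Two homogeneous halves at 50/100 plus sigma=5 Gaussian noise."""
    rng = np.random.default_rng(42)
    data = np.full((24, 16, 16), 50.0)
    data[12:] = 100.0
    noisy = data + rng.normal(0, 5.0, size=data.shape)
    return data, noisy
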
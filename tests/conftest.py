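import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from crumplefet import IonBathSpec, SurfaceModel  # noqa: E402
from crumplefet.datatypes import DEFAULT_CHARGES, ParticleFrame  # noqa: E402


@pytest.fixture
def bath():
    return IonBathSpec(seed=0)


@pytest.fixture
def flat_surface():
    return SurfaceModel("flat")


@pytest.fixture
def sin_surface():
    return SurfaceModel("sinusoid")


@pytest.fixture
def small_flat_frame(flat_surface):
    """Three ions at known heights above a flat 10×10×5 nm box."""
    pos = np.array([[1.0, 2.0, 0.5], [3.0, 4.0, 1.5], [5.0, 6.0, 2.5]])
    species = np.array(["Na+", "Na+", "Cl-"], dtype=object)
    return ParticleFrame(pos, species, dict(DEFAULT_CHARGES),
                         np.array([10.0, 10.0, 5.0]), surface=flat_surface)
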
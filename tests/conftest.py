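import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fractalct.phantom import (
    EllipsoidSpec,
    MuscleSpec,
    PhantomSpec,
    RimSpec,
    VesselSpec,
)
from fractalct.types import PhaseStack

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Compact phantom (48×48×32) for fast pipeline tests."""
    return PhantomSpec(
        grid_shape=(48, 48, 32),
        core=EllipsoidSpec(centre_mm=(16.8, 16.8, 11.2), semi_axes_mm=(7.0, 6.0, 4.0)),
        rim=RimSpec(thickness_mm=3.5),
        portal_vein=VesselSpec(centre_xy_mm=(27.0, 27.0), radius_mm=2.5),
        muscle=MuscleSpec(corner_mm=(2.1, 2.1, 2.1), size_mm=(7.0, 7.0, 7.0)),
        seed=seed,
    )


@pytest.fixture
def small_spec() -> PhantomSpec:
    return small_phantom_spec()


@pytest.fixture
def flat_stack() -> PhaseStack:
    """Constant-valued 3-phase stack (the flat-texture limit)."""
    return PhaseStack(np.full((8, 8, 8, 3), 40.0), (1.0, 1.0, 1.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
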
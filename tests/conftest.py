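import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazebench import (
    CohortConfig,
    PresentationCondition,
    ScreenGeometry,
    default_scenes,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_geometry() -> ScreenGeometry:
    """720x404 clip centred on a 1024x768 display."""
    return ScreenGeometry.centered(1024, 768, 720, 404)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-factorial synthetic dataset: 7 observers x 2 clips
    x 4 conditions, default observer parameters."""
    scenes = default_scenes(2, seed=11)
    return generate_cohort(CohortConfig(n_observers=7, master_seed=11), scenes)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


@pytest.fixture(params=list(PresentationCondition), ids=lambda c: c.value)
def condition(request) -> PresentationCondition:
    return request.param
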
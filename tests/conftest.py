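import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from petkin.synthetic_data import (  # noqa: E402
    AORTA_SHAPE,
    RV_SHAPE,
    TUMOR_PRESET,
    generate_input,
)
from petkin.tac_io import AORTA, RIGHT_VENTRICLE, default_schedule  # noqa: E402


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def aorta_input(schedule):
    return generate_input(AORTA_SHAPE, schedule, label=AORTA)


@pytest.fixture(scope="session")
def rv_input(schedule):
    return generate_input(RV_SHAPE, schedule, label=RIGHT_VENTRICLE)


@pytest.fixture(scope="session")
def tumor_params():
    return TUMOR_PRESET.params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
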
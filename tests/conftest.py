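import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import t2mapping as t2

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grase():
    return t2.build_schedule("GraSE")


@pytest.fixture(scope="session")
def mese():
    return t2.build_schedule("MESE")


@pytest.fixture(scope="session")
def t2prep():
    return t2.build_schedule("T2prep")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
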
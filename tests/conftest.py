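import dataclasses

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from twinplat import synth
from twinplat.synth import SwayParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 2000.0


@pytest.fixture(scope="session")
def geometry():
    return synth.default_geometry()


@pytest.fixture(scope="session")
def subject():
    return synth.default_subject()


@pytest.fixture(scope="session")
def quiet_subject():
    """Subject with every stochastic component switched off."""
    return dataclasses.replace(
        synth.default_subject(),
        sway=SwayParams(sd_ap_cm=0.0, sd_ml_cm=0.0),
        weight_fluctuation_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
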
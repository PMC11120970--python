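import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from axoplast import SceneParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def control_params() -> SceneParams:
    """Control-condition ankyrinG geometry (start 4.5, max 13.6, end 26.9 um)."""
    return SceneParams(profile_length_um=35.0, noise_sigma=0.0)


@pytest.fixture
def ring_params() -> SceneParams:
    """Noiseless ~2 um ring profile at the 190 nm / 40 nm study grid."""
    return SceneParams(profile_length_um=2.0, noise_sigma=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240510)


def replace(params, **kw):
    return dataclasses.replace(params, **kw)
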
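import numpy as np
import pytest

from stomakit import SceneParams, generate_scene
from stomakit.calibration import CALIBRATION_4X


@pytest.fixture(scope="session")
def calibration():
    return CALIBRATION_4X


@pytest.fixture(scope="session")
def small_scene():
    """A modest wheat-like scene with marginal placement disabled."""
    return generate_scene(SceneParams(seed=7, allow_marginal=False))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
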
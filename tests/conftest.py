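import numpy as np
import pytest
from hypothesis import settings

from mechanofeedback import model as M

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def quiet_params():
    """Noise-free fast subsystem only (no remodeling, no feedback)."""
    return M.ModelParams(noise_sigma=0.0, feedback_enabled=False,
                         remodeling_enabled=False)


@pytest.fixture
def balanced_state(quiet_params):
    return M.default_state(quiet_params)


@pytest.fixture
def balanced_tension(quiet_params, balanced_state):
    return M.fixed_point_tension(quiet_params, balanced_state)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
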
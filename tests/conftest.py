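import numpy as np
import pytest

from isrsim.presets import coarse_demo


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def demo_config():
    """The desk-scale vessel used for end-to-end runs."""
    return coarse_demo()


@pytest.fixture
def mid_inputs():
    """Midpoints of the three uncertain inputs."""
    return {"flow_velocity": 0.48, "deployment_depth": 0.11,
            "regen_time": 19.0}
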
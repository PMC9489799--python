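import numpy as np
import pytest

from aggremorph.synthetic import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A light-weight simulation: few aggregates, short acquisition."""
    return SimulationParams(
        n_aggregates=20,
        n_frames=2000,
        p_bind=2e-3,
        background_rate=0.0,
        n_fiducials=0,
        fov_size=20000.0,
    )
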
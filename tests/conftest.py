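import numpy as np
import pytest

from alveotension import LungModel, VentSettings


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def ards_lung():
    """Moderate-ARDS baby lung: half-normal compliance, V_rest estimated."""
    return LungModel(C_obs=40.0, C_norm=80.0, FRC_pred=2400.0)


@pytest.fixture
def vent():
    return VentSettings(V_T=400.0, PEEP=10.0, f=20.0, Pt=15.0)
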
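import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scmskit as sk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params():
    """Reference bivalent rate parameters (k2 derives to 0.136 min^-1)."""
    return sk.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def ref_saturation(ref_params):
    """Endpoint saturation simulation on a 25-point 1-1000 nM grid, 120 min."""
    grid = np.logspace(-9, -6, 25)
    return sk.simulate_saturation_curve(ref_params, grid)
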
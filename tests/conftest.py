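import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import proteodyn as P

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_connectome() -> P.Connectome:
    """21-node synthetic network with all seed regions and lobes present."""
    return P.generate_synthetic_connectome(21, 40, rng_seed=0)


@pytest.fixture(scope="session")
def default_series(small_connectome):
    """Default 30-year disease run on the small network (shared, read-only)."""
    return P.integrate_proteopathy(
        P.initialize_state(small_connectome), P.SpreadingParams(), P.DamageParams()
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
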
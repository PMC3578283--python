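import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynamem as dm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    """Ideal sublattice spec at the headline correlation level b = 0.2."""
    return dm.SublatticeSpec.ideal(0.2)


@pytest.fixture(scope="session")
def seeds(spec):
    """Canonical seed family as a name -> activity-vector dict."""
    return dict(dm.seed_family(spec))


@pytest.fixture(scope="session")
def pseudo_params():
    """Pseudo-constant region: weak short-term plasticity."""
    return dm.ModelParams(T=0.2, tau_R=4, tau_F=2)


@pytest.fixture(scope="session")
def depression_params():
    return dm.ModelParams(T=0.2, tau_R=10, tau_F=2)


@pytest.fixture(scope="session")
def facilitation_params():
    return dm.ModelParams(T=0.2, tau_R=4, tau_F=24)


@pytest.fixture(scope="session")
def small_patterns():
    """A small correlated pattern draw shared across tests."""
    return dm.generate_patterns(N=400, p=3, b=0.2, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
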
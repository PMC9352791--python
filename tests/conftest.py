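import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfarm import models, taskgen

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: generating parameter values used across tests: the winning model's
#: population means (short / long horizon)
GEN_PARAMS = dict(
    epsilon_short=0.099, epsilon_long=0.134,
    eta_short=1.919, eta_long=2.884,
    sigma0_short=1.085, sigma0_long=1.186,
    Q0=5.0,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Task configuration with a short session (40 trials per horizon)."""
    return taskgen.GenerativeConfig(n_trials_per_horizon=40)


@pytest.fixture(scope="session")
def session_default():
    """One full-size session (400 trials)."""
    return taskgen.make_session("p0", seed=123)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return taskgen.make_session("p0", seed=7, cfg=small_cfg)


@pytest.fixture(scope="session")
def winning_spec():
    return models.get_model("Thompson+eta+eps")


@pytest.fixture(scope="session")
def simulated_choices(session_default, winning_spec):
    rng = np.random.default_rng(99)
    return models.simulate_session(winning_spec, GEN_PARAMS, session_default, rng)
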
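import numpy as np
import pytest

from depthsim.agent import AgentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    """Shipped default agent configuration."""
    return AgentConfig()


@pytest.fixture
def gentle_cfg():
    """Unit precisions/gains: convenient for the printed-ODE (dynamic
    error-unit) regime, where the relaxation time constant equals the
    precision."""
    return AgentConfig(
        pi_r=1.0, pi_p=1.0, pi_pp=1.0, pi_c=1.0, pi_v=1.0,
        k_a=1.0, k_theta=1.0, k_r=1.0, k_c=1.0, k_action=1.0,
        lam=1.0, instantaneous_errors=False,
    )
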
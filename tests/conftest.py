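import numpy as np
import pytest

from foragesim import AgentPolicy, TrialConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def e1_feature():
    return TrialConfig(
        variant="E1_avoid",
        predation_role="distracted",
        target_condition="feature",
        wolf_behavior="pack",
        wolf_speed=54.0,
    )


@pytest.fixture
def e1_hunted():
    return TrialConfig(
        variant="E1_avoid",
        predation_role="hunted",
        target_condition="feature",
        wolf_behavior="pack",
        wolf_speed=78.0,
    )


@pytest.fixture
def e2_hunted():
    return TrialConfig(
        variant="E2_freeze",
        predation_role="hunted",
        target_condition="feature",
        wolf_behavior="pack",
        wolf_speed=78.0,
    )


@pytest.fixture
def e3_config():
    return TrialConfig(
        variant="E3_reward",
        predation_role="distracted",
        target_condition="reward",
        wolf_behavior="lone",
        wolf_speed=78.0,
    )


@pytest.fixture
def uniform_policy():
    return AgentPolicy(switch_prob=None, label="uniform")
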
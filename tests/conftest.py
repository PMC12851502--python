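import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import painpomdp as pp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return pp.make_injury_pomdp()


@pytest.fixture(scope="session")
def default_solution(default_spec):
    return pp.value_iteration(default_spec)


@pytest.fixture(scope="session")
def three_action_spec():
    return pp.make_injury_pomdp({"actions": "act,rest,query"})


@pytest.fixture(scope="session")
def three_action_solution(three_action_spec):
    return pp.value_iteration(three_action_spec)


@pytest.fixture(scope="session")
def two_action_spec():
    return pp.make_test_fixture("two_action")


@pytest.fixture(scope="session")
def tiny_spec():
    return pp.make_test_fixture("tiny_obs")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
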
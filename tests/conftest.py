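import pytest

from ruleout.datasets import (
    hong_kong_costs,
    hong_kong_event_probs,
    hong_kong_model,
    hong_kong_phi_cohort,
)


@pytest.fixture(scope="session")
def hk_cohort():
    return hong_kong_phi_cohort()


@pytest.fixture(scope="session")
def hk_probs():
    return hong_kong_event_probs()


@pytest.fixture(scope="session")
def hk_costs():
    return hong_kong_costs()


@pytest.fixture(scope="session")
def hk_model():
    return hong_kong_model(35.0)


@pytest.fixture(scope="session")
def hk_params(hk_model):
    return hk_model.params()
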
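import pytest

from glycferm.fixtures import build_core_model
from glycferm.registry import core_scenarios
from glycferm.scenarios import build_scenario_model


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def scenarios():
    return core_scenarios()


@pytest.fixture(scope="session")
def h2_model(core_model, scenarios):
    """Base-case (H2-enabled) curated model."""
    return build_scenario_model(core_model, scenarios["h2_mode"])


@pytest.fixture(scope="session")
def pdo_model(core_model, scenarios):
    """1,2-PDO-enabled curated model (reversible hydrogenase removed)."""
    return build_scenario_model(core_model, scenarios["pdo_mode"])


@pytest.fixture(scope="session")
def fp_capped_model(core_model, scenarios):
    return build_scenario_model(core_model, scenarios["fp_capped"])
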
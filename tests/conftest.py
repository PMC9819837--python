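import pytest
from hypothesis import settings

import markovcea as mc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config() -> mc.AnalysisConfig:
    return mc.paper_base_case()


@pytest.fixture(scope="session")
def model(base_config) -> mc.TwoArmModel:
    return base_config.two_arm_model()


@pytest.fixture(scope="session")
def base_result(model):
    return model.run()


@pytest.fixture(scope="session")
def palbociclib(model) -> mc.StrategyInputs:
    return model.comparator


@pytest.fixture(scope="session")
def ribociclib(model) -> mc.StrategyInputs:
    return model.intervention
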
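import pytest

from endocea.scenario import builtin_scenario, run_scenario


@pytest.fixture(scope="session")
def base_config():
    return builtin_scenario("keynote775_base")


@pytest.fixture(scope="session")
def pmmr_config():
    return builtin_scenario("keynote775_pmmr")


@pytest.fixture(scope="session")
def base_result(base_config):
    return run_scenario(base_config.build())


@pytest.fixture(scope="session")
def pmmr_result(pmmr_config):
    return run_scenario(pmmr_config.build())
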
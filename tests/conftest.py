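import pytest

from cbtroi import load_config


@pytest.fixture(scope="session")
def cfg():
    """Bundled base-case configuration (parameters, ledgers, schedule)."""
    return load_config()


@pytest.fixture(scope="session")
def base_scenario(cfg):
    return cfg.scenario()


@pytest.fixture(scope="session")
def base_result(base_scenario):
    return base_scenario.run()
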
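import pytest

from karsim import build_table1_config, build_table2_config, engine


@pytest.fixture(scope="session")
def table1_config():
    return build_table1_config()


@pytest.fixture(scope="session")
def table2_config():
    return build_table2_config()


@pytest.fixture(scope="session")
def table1_run(table1_config):
    """Clean cargo run over the full printed range, departures active."""
    return engine.run(table1_config, n_rounds=48)


@pytest.fixture(scope="session")
def table2_run(table2_config):
    """Clean enzyme run over the full printed range."""
    return engine.run(table2_config, n_rounds=23)
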
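import pytest

from fncea import load_parameters


@pytest.fixture(scope="session")
def config():
    return load_parameters()


@pytest.fixture(scope="session")
def params(config):
    return config[0]


@pytest.fixture(scope="session")
def psa_dists(config):
    return config[1]


@pytest.fixture(scope="session")
def strategies(config):
    return config[2]


@pytest.fixture(scope="session")
def by_id(strategies):
    return {s.id: s for s in strategies}
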
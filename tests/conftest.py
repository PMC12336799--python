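import pytest

from tg263harm import BackendConfig, MockBackend, load_bundled_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_bundled_lexicon()


@pytest.fixture(scope="session")
def mock_backend(lexicon):
    return MockBackend(lexicon)


@pytest.fixture()
def det_config():
    return BackendConfig(temperature=0.0)
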
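import pytest

from clinscheme import SynthConfig, generate_corpus, load_default_scheme


@pytest.fixture(scope="session")
def scheme():
    return load_default_scheme()


@pytest.fixture(scope="session")
def corpus(scheme):
    """A small deterministic synthetic corpus shared across tests."""
    return generate_corpus(scheme, SynthConfig(seed=11, n_docs=12))
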
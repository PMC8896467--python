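import pytest

from duplexpipe import duplexsim as sim


@pytest.fixture(scope="session")
def gene():
    """The deterministic synthetic FGFR3-like reference used across tests."""
    return sim.synthetic_gene()


@pytest.fixture(scope="session")
def model(gene):
    return gene[0]


@pytest.fixture(scope="session")
def layout(gene):
    return gene[1]
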
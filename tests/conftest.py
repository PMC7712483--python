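import pytest

from pompe_nbs import load_default_kb, load_fixtures


@pytest.fixture(scope="session")
def kb():
    return load_default_kb()


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def confirmed(fixtures):
    """The 33 confirmed IOPD+LOPD records."""
    return fixtures.table2


@pytest.fixture(scope="session")
def suspected(fixtures):
    """The 30 suspected-LOPD records."""
    return fixtures.table3
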
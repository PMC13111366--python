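import pytest
from hypothesis import settings

from pgxscreen.fixtures import load_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    records, meta = load_fixture("table1")
    return records, meta


@pytest.fixture(scope="session")
def table2():
    records, meta = load_fixture("table2")
    return records, meta


@pytest.fixture(scope="session")
def table1_markings():
    return load_fixture("table1_markings")


@pytest.fixture(scope="session")
def table2_markings():
    return load_fixture("table2_markings")


@pytest.fixture(scope="session")
def haplotypes():
    return load_fixture("table3_xref")


@pytest.fixture(scope="session")
def table3_rows():
    return load_fixture("table3_rows")
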
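import pytest

from lipichrom import build_fixture_index_table, load_table1, load_table3


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def index_table():
    return build_fixture_index_table()
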
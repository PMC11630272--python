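import pytest

from oleotec import default_assumption_set, load_strain_table


@pytest.fixture()
def default_set():
    return default_assumption_set()


@pytest.fixture(scope="session")
def strain_records():
    return load_strain_table()
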
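import pytest
from hypothesis import settings

from heatcross import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")
from heatcross.io_formats import load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def f1_markers():
    return load_fixture("f1_markers")


@pytest.fixture(scope="session")
def crosses():
    return load_fixture("crosses")


@pytest.fixture(scope="session")
def sw5():
    return synthetic.sw5_fixture(seed=11)


@pytest.fixture(scope="session")
def ve1():
    return synthetic.ve1_caps_fixture(seed=11)


@pytest.fixture(scope="session")
def ve1_nested():
    return synthetic.ve1_nested_fixture(seed=11)
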
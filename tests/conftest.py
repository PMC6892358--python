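import pytest

from syntenykit.fixtures import load_usecase, make_usecase_fixture


@pytest.fixture(scope="session")
def lung_fixture(tmp_path_factory):
    return make_usecase_fixture("lung", tmp_path_factory.mktemp("lung"))


@pytest.fixture(scope="session")
def t2dm_fixture(tmp_path_factory):
    return make_usecase_fixture("t2dm", tmp_path_factory.mktemp("t2dm"))


@pytest.fixture(scope="session")
def lung(lung_fixture):
    return load_usecase(lung_fixture)


@pytest.fixture(scope="session")
def t2dm(t2dm_fixture):
    return load_usecase(t2dm_fixture)
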
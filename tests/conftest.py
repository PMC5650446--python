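import pytest

from hepacea import CostUtilityModel, load_paper_fixture


@pytest.fixture(scope="session")
def fixture():
    return load_paper_fixture()


@pytest.fixture(scope="session")
def model(fixture):
    return CostUtilityModel.from_fixture(fixture)


@pytest.fixture(scope="session")
def sbrt(fixture):
    return fixture.strategies["sbrt"]


@pytest.fixture(scope="session")
def proton(fixture):
    return fixture.strategies["proton"]
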
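import pytest

from spanfold import EnergyModel, RnaSequence


@pytest.fixture(scope="session")
def zero_model():
    return EnergyModel.zero()


@pytest.fixture(scope="session")
def default_model():
    return EnergyModel.default()


@pytest.fixture()
def gaaac():
    return RnaSequence("gaaac", "GAAAC")
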
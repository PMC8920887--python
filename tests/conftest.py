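import pytest

import swbair as sb


@pytest.fixture(scope="session")
def builtin_chemicals():
    return sb.load_builtin_chemicals()


@pytest.fixture(scope="session")
def chem_map(builtin_chemicals):
    return {c.name: c for c in builtin_chemicals}


@pytest.fixture(scope="session")
def benzene(chem_map):
    return chem_map["Benzene"]


@pytest.fixture(scope="session")
def chlorpyrifos(chem_map):
    return chem_map["Chlorpyrifos"]


@pytest.fixture
def sampler():
    return sb.SamplerSpec(mass_g=4.76, density_g_per_ml=1.10)
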
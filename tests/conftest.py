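import pytest
from hypothesis import settings

from nibam.chemistry import ReferenceEngine

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from nibam.gbam import load_models
from nibam.synthetic import make_water, reference_water


@pytest.fixture(scope="session")
def engine():
    return ReferenceEngine()


@pytest.fixture(scope="session")
def models():
    return load_models()


@pytest.fixture(scope="session")
def ref_water():
    return reference_water()


@pytest.fixture(scope="session")
def soft_water():
    return make_water(ph=6.5, doc=0.5, hardness=30.0, water_id="soft")


@pytest.fixture(scope="session")
def hard_water():
    return make_water(ph=8.3, doc=10.0, hardness=250.0, water_id="hard")
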
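import pytest

from mitoswell import ModelParameters, PhysicalConstants


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def constants() -> PhysicalConstants:
    return PhysicalConstants()
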
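import pytest

from hhsym.membrane_model import MembraneParams, Protocol


@pytest.fixture(scope="session")
def params() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def rest_protocol() -> Protocol:
    return Protocol(kind="current_clamp", segments=((30.0, 0.0),))


@pytest.fixture(scope="session")
def spike_protocol() -> Protocol:
    return Protocol(kind="current_clamp", segments=((50.0, 10.0),))
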
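import pytest

from coopres import ModelParams, PassageProtocol


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Default (measured/fitted) kinetic parameters."""
    return ModelParams()


@pytest.fixture(scope="session")
def protocol() -> PassageProtocol:
    """Reference condition: 100 µg/ml ampicillin, 100x dilution, 23 h."""
    return PassageProtocol()
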
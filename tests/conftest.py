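import pytest

from iorfield import ModelParams, ior_sweep


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_sweep(params):
    """IOR curve over the six standard CTOAs, expectation input on."""
    return ior_sweep(params=params, expectation_enabled=True)


@pytest.fixture(scope="session")
def noexp_sweep(params):
    """IOR curve over the six standard CTOAs, expectation input off."""
    return ior_sweep(params=params, expectation_enabled=False)
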
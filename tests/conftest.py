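import pytest

from osmofreeze import generate_bbd, presets


@pytest.fixture(scope="session")
def factor_space():
    return presets.FACTOR_SPACE


@pytest.fixture(scope="session")
def bbd_runs(factor_space):
    return generate_bbd(factor_space, n_center=3)


@pytest.fixture(scope="session")
def surface_models():
    return presets.surface_models()
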
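import pytest

from cytomorph.synthgen import OpticsModel, StreamModel


@pytest.fixture
def optics():
    return OpticsModel()


@pytest.fixture
def quiet_optics():
    """Noise-free optics for exact-recovery fixtures."""
    return OpticsModel(noise_sd=0.0)


@pytest.fixture
def stream():
    return StreamModel()
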
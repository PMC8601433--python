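import pytest

from pdmsphantom.phantom_model import SpectralGrid


@pytest.fixture(scope="session")
def default_grid() -> SpectralGrid:
    return SpectralGrid()
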
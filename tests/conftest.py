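import pytest

from pindyn.context import SpectrometerContext


@pytest.fixture(scope="session")
def ctx() -> SpectrometerContext:
    """Spectrometer context at the study field (700.33 MHz ¹H)."""
    return SpectrometerContext()
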
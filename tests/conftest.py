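import numpy as np
import pytest

from duvdecon import RamanSpectrum, StandardLibrary, SyntheticConfig


@pytest.fixture
def fingerprint_axis():
    """2 cm^-1 grid over the organic fingerprint range."""
    return np.arange(800.0, 1801.0, 2.0)


@pytest.fixture
def full_axis():
    """Grid wide enough to include the atmospheric N2 region."""
    return np.arange(400.0, 2401.0, 2.0)


@pytest.fixture
def dntp_library(fingerprint_axis):
    return StandardLibrary.from_tier("dNTP", fingerprint_axis)


@pytest.fixture
def ramp_spectrum():
    shift = np.arange(800.0, 900.0, 2.0)
    return RamanSpectrum(shift, 2.0 * shift + 7.0, {"label": "ramp"})


@pytest.fixture
def cell_fixture():
    """Factory for seeded cell-like synthetic acquisitions."""
    from duvdecon import end_to_end_fixture

    def make(seed=0, **overrides):
        return end_to_end_fixture(SyntheticConfig.cell_like(seed=seed,
                                                            **overrides))

    return make
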
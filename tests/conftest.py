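import numpy as np
import pytest
from hypothesis import settings

from adaptrans import AdapTransParams, Cochleagram

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def band_freqs():
    return np.geomspace(500.0, 22627.0, 8)


@pytest.fixture
def params(band_freqs):
    return AdapTransParams.from_frequencies(band_freqs, dt=0.005)


@pytest.fixture
def single_band():
    """One-band parameter set at the reference (w=0.5, a=0.6) operating point."""
    return AdapTransParams(w=[0.5], a_on=[0.6], a_off=[0.6], dt=0.005,
                           band_freqs=[1000.0])


@pytest.fixture
def step_stim(band_freqs):
    values = np.zeros((8, 300))
    values[:, 50:200] = 1.0
    return Cochleagram(values=values, band_freqs=band_freqs, dt=0.005)
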
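import numpy as np
import pytest

from chromakin import SteadySpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def gauss(x, center, fwhm, amp=1.0):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp * np.exp(-0.5 * ((np.asarray(x, float) - center) / sigma) ** 2)


@pytest.fixture
def gaussian_spectrum():
    """Factory for single- or multi-band Gaussian spectra on an nm grid."""

    def build(bands, lo=630.0, hi=800.0, n=681, kind="absorption", temperature_K=None):
        wl = np.linspace(lo, hi, n)
        v = np.zeros_like(wl)
        for c, fw, a in bands:
            v += gauss(wl, c, fw, a)
        return SteadySpectrum(wl, v, kind, temperature_K)

    return build
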
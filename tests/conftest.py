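import numpy as np
import pytest

from uspio_t2star import DEFAULT_ECHO_TIMES_MS, EchoSeries
from uspio_t2star.phantom import decay_signal


@pytest.fixture(scope="session")
def te8():
    """Default 8-echo scheme, 2.1-17.1 ms."""
    return np.array(DEFAULT_ECHO_TIMES_MS)


@pytest.fixture(scope="session")
def make_series(te8):
    """Factory for noiseless (or Rician-noisy) mono-exponential series."""

    def _make(r2star, s0=1000.0, sigma=0.0, rng=None, te=None, offset=0.0,
              background_sigma=None):
        te = te8 if te is None else np.asarray(te, float)
        clean = np.asarray(decay_signal(s0, r2star, te)) + offset
        if sigma > 0:
            g1 = rng.normal(0.0, sigma, te.size)
            g2 = rng.normal(0.0, sigma, te.size)
            clean = np.sqrt((clean + g1) ** 2 + g2**2)
        return EchoSeries(te, clean, background_sigma=background_sigma)

    return _make
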
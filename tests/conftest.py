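import numpy as np
import pandas as pd
import pytest

from srmquant.peaks import Trace


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def gaussian_trace():
    """Single clean Gaussian peak, apex 1000 at t=60 s, sigma 3 s."""
    t = np.arange(0.0, 120.5, 0.5)
    y = 1000.0 * np.exp(-0.5 * ((t - 60.0) / 3.0) ** 2)
    return Trace("S1", ("PEP", "y5", 1), "light", t, y)


def make_trace(times, intensities, label="light", frag="y5"):
    return Trace("S1", ("PEP", frag, 1), label,
                 np.asarray(times, float), np.asarray(intensities, float))


@pytest.fixture
def cohort_labels():
    def _labels(manifest):
        groups = pd.Series({r.sample_id: r.group for r in manifest})
        return groups.map({"cancer": 1, "non-cancer": 0}).dropna().astype(int)
    return _labels
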
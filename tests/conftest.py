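import numpy as np
import pytest

from shamtrack.protocol import DEFAULT_PROTOCOLS, build_ideal_curve
from shamtrack.synth import StudyDesign, simulate_study


@pytest.fixture(scope="session")
def ideal_active_2mA():
    return build_ideal_curve(DEFAULT_PROTOCOLS["active_2mA"])


@pytest.fixture(scope="session")
def ideal_sham_2mA():
    return build_ideal_curve(DEFAULT_PROTOCOLS["sham_2mA"])


@pytest.fixture(scope="session")
def small_study():
    """A small (4 per strength) synthetic study plus its ground truth."""
    return simulate_study(StudyDesign(n_per_strength=4), seed=20240901)


@pytest.fixture(scope="session")
def full_study():
    """A default-size (32 per strength) synthetic study plus ground truth."""
    return simulate_study(StudyDesign(), seed=20240902)


def brute_force_xcorr(x, y, max_lag):
    """Independent O(N*L) double-loop oracle for the normalised lagged
    cross-correlation with zero padding and a global normaliser."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.zeros(lags.size)
    for i, m in enumerate(lags):
        acc = 0.0
        for j in range(n):
            k = j + m
            if 0 <= k < n:
                acc += x[j] * y[k]
        r[i] = acc / denom
    return lags, r
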
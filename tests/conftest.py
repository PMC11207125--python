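import numpy as np
import pytest

import rfacontrol as rc


@pytest.fixture(scope="session")
def plant():
    """Canonical 9th-order continuous plant, Routh-refined denominator."""
    return rc.canonical_plant("routh_refined")


@pytest.fixture(scope="session")
def plant_printed():
    return rc.canonical_plant("as_printed")


@pytest.fixture(scope="session")
def tuned_gains():
    return rc.REFERENCE_GAINS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_arx_timeseries(a1=-0.5, b1=1.0, n=200, noise_sd=0.0, seed=0):
    """Data generated exactly by y(k) = -a1*y(k-1) + b1*u(k-1) + noise."""
    rng = np.random.default_rng(seed)
    u = np.sin(0.3 * np.arange(n)) + 0.5 + 0.1 * rng.normal(size=n)
    y = np.zeros(n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for k in range(1, n):
        y[k] = -a1 * y[k - 1] + b1 * u[k - 1] + noise[k]
    return rc.TimeSeries(np.arange(n, dtype=float), u, y)
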
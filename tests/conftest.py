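import numpy as np
import pytest

from dendelay.devices import DelayBank, DelayDistribution
from dendelay.raster import SpikeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def measured_dist():
    return DelayDistribution.measured()


@pytest.fixture
def small_bank():
    """2 channels x 4 synapses with hand-picked delays on a 5 ms grid."""
    delays = np.array([[0.021, 0.035, 0.048, 0.058], [0.005, 0.010, 0.015, 0.020]])
    return DelayBank(delays, dt=5e-3)


def random_raster(rng, n_channels=3, n_bins=40, rate=0.15, dt=5e-3):
    counts = rng.poisson(rate, size=(n_channels, n_bins))
    return SpikeRaster(counts, dt=dt)


@pytest.fixture
def raster_factory(rng):
    return lambda **kw: random_raster(rng, **kw)
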
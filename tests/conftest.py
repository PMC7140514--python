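import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trains(rng, n_electrodes, duration_s, rate_hz):
    """Random homogeneous Poisson spike trains for property tests."""
    from neurophenolab.mea import SpikeTrainSet
    trains = []
    for _ in range(n_electrodes):
        n = rng.poisson(rate_hz * duration_s)
        trains.append(np.unique(rng.uniform(0, duration_s, size=n)))
    return SpikeTrainSet(trains, duration_s)
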
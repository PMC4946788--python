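import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from asset.simulate import SSESpec, generate_model, inject_sse
from asset.spikedata import BinConfig, SpikeTrainSet, bin_spike_trains


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spikes():
    """Four neurons, 100 ms window, hand-placed spikes."""
    return SpikeTrainSet(
        trains=[
            [0.001, 0.002, 0.031],
            [0.012],
            [],
            [0.010, 0.055, 0.090],
        ],
        t_start=0.0,
        t_stop=0.100,
    )


@pytest.fixture
def poisson_set(rng):
    """20 stationary Poisson trains at 15 Hz on 1 s."""
    return generate_model(0, seed=rng, n_neurons=20)


@pytest.fixture
def bins_1s():
    return BinConfig.from_interval(0.0, 1.0, 0.005)


@pytest.fixture
def injected_model0():
    """Model-0 background with the default 7x5 SSE injected (seeded)."""
    background = generate_model(0, seed=7)
    data, truth = inject_sse(background, SSESpec(), bin_width=0.005, seed=8)
    return data, truth
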
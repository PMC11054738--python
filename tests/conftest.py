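import numpy as np
import pytest

from huespec.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Desk-scale study: 3 fruits/group, 3 days, small frames."""
    return SimulationConfig(
        n_fruit_per_group=3,
        sampling_days=(0, 7, 14),
        frame_px=48,
        diameter_px=28,
        seed=7,
    )


def random_spectrum(rng, n_bins=360, low=0.2, high=1.0):
    """A strictly positive random polar spectrum (no degenerate zero arcs)."""
    return rng.uniform(low, high, n_bins)
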
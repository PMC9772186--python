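import numpy as np
import pytest

from reefcore import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def clean_core():
    """Ten noise-free years at 1 cm/yr, collected at a year boundary."""
    spec = simulate.CoreSimSpec(
        n_years=10, extension_by_year=1.0, sample_spacing=0.1, noise_sd=0.0,
        collection_year=2012,
    )
    return simulate.simulate_core(spec)


@pytest.fixture
def stressed_core():
    """One 2 mm, 4 SD anomaly in 1998, no noise."""
    spec = simulate.CoreSimSpec(
        n_years=10, collection_year=2005, noise_sd=0.0,
        stress_events=((1998, 4.0, 2.0),),
    )
    return simulate.simulate_core(spec)
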
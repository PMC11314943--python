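import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import radarposture as rp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return rp.GridSpec()


@pytest.fixture(scope="session")
def placement():
    return rp.default_placement()


@pytest.fixture(scope="session")
def sim_params():
    return rp.SimParams(n_pulses=8)


@pytest.fixture(scope="session")
def small_records(placement, sim_params):
    """6 subjects x 9 postures, thin blanket, 1 trial: 54 samples."""
    records, manifest = rp.generate_dataset(
        6, rp.FINE_LABELS, ("thin",), 1, placement=placement,
        params=sim_params, seed=11,
    )
    return records, manifest


@pytest.fixture(scope="session")
def small_views(small_records, placement, grid):
    """Model-ready arrays for the 54-sample fixture."""
    records, _ = small_records
    x, postures, subjects, ids = rp.views_from_samples(
        records, placement=placement, grid=grid, input_size=32
    )
    y = rp.encode_labels(postures, "coarse")
    return x, y, np.asarray(subjects)
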
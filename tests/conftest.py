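import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from mobiscale.synthetic_data import generate_trajectory, random_itinerary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_trajectory():
    """A 5-dwell synthetic trajectory plus its ground-truth staypoints."""
    plan = random_itinerary(n_staypoints=5, seed=7, jitter=5.0,
                            dwell_range=(300.0, 600.0))
    traj, truth = generate_trajectory(plan, seed=7)
    return plan, traj, truth
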
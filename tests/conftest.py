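import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by recovery-style tests."""
    from leafdeo.simulate import SimConfig, simulate_dataset

    return simulate_dataset(SimConfig(seed=7, n_og=120))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, mu, phi, size):
    """Reference NB sampler used by tests (size = draws)."""
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)
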
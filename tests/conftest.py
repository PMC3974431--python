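import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from wingmorph import SyntheticSpec, simulate_dataset

# the novelty warning is informative noise in tests that assign unknowns
logging.getLogger("wingmorph.assign").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def three_group_dataset():
    """Small well-separated 3-group dataset used across modules."""
    spec = SyntheticSpec(seed=7, groups=(("A", 15), ("B", 15), ("C", 15)))
    return spec, simulate_dataset(spec)


def random_configuration(rng, k=18, scale=1.0):
    return rng.normal(scale=scale, size=(k, 2))
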
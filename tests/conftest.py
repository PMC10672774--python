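import numpy as np
import pytest

from lasim import Arm, load_fixture, simulate_cohort
from lasim.simulator import default_grid

ALL_ARM_LABELS = ["Pro", "Lid", "Mep", "Bup", "Lid+Adr"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def all_arms():
    return [Arm.from_label(a) for a in ALL_ARM_LABELS]


@pytest.fixture(scope="session")
def pop_model2():
    return load_fixture("table1_model2")


@pytest.fixture(scope="session")
def small_cohort(pop_model2, all_arms):
    """Three animals, five arms, raw-style grid — shared across tests."""
    return simulate_cohort(
        pop_model2, 3, all_arms, default_grid(100), model_variant=2, seed=99
    )
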
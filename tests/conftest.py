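import numpy as np
import pytest

from pfcrosslink.grm import ItemParameters, make_grid
from pfcrosslink.simulate import SyntheticConfig, make_item_banks, simulate_sample


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def dense_grid():
    return make_grid(n_nodes=2001, bounds=(-8.0, 8.0))


@pytest.fixture
def binary_item():
    return ItemParameters("bin", 2.0, (0.0,))


@pytest.fixture
def small_bank():
    return [
        ItemParameters("i1", 1.4, (-1.0, 0.5)),
        ItemParameters("i2", 2.2, (-0.3, 1.2)),
        ItemParameters("i3", 0.9, (-2.0, 0.0)),
    ]


def random_bank(rng, n_items=10, n_cats=3, a_range=(0.8, 3.0)):
    items = []
    for i in range(n_items):
        a = rng.uniform(*a_range)
        b = np.sort(rng.uniform(-2.5, 2.5, size=n_cats - 1))
        while np.any(np.diff(b) < 0.15):
            b = np.sort(rng.uniform(-2.5, 2.5, size=n_cats - 1))
        items.append(ItemParameters(f"r{i}", a, tuple(b)))
    return items


@pytest.fixture(scope="session")
def study_banks():
    """Default anchor/linked banks under the study conditions, seed 123."""
    cfg = SyntheticConfig(seed=123)
    rng = np.random.default_rng(123)
    return make_item_banks(cfg, rng)


@pytest.fixture(scope="session")
def study_dataset(study_banks):
    """One clean dataset at the study's subsample sizes (185/172/262)."""
    cfg = SyntheticConfig(seed=123)
    return simulate_sample(study_banks, cfg, seed=456)
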
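import numpy as np
import pytest

from hemiflip.synthdata import (
    CohortSpec,
    make_symmetric_atlas,
    synthetic_hub_table,
)


@pytest.fixture(scope="session")
def small_hub_table():
    """4 left + 4 right hubs on the 8x8x4 test grid (2 language hubs)."""
    return synthetic_hub_table(4, 4, (8, 8, 4), 3.0)


@pytest.fixture(scope="session")
def small_atlas(small_hub_table):
    return make_symmetric_atlas((8, 8, 4), 3.0, 5.0, small_hub_table)


@pytest.fixture(scope="session")
def full_hub_table():
    """The canonical 9 + 11 hub configuration on a compact grid."""
    return synthetic_hub_table(9, 11, (12, 12, 8), 3.0)


@pytest.fixture(scope="session")
def full_atlas(full_hub_table):
    return make_symmetric_atlas((12, 12, 8), 3.0, 5.0, full_hub_table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_spec(**kw):
    """A fast cohort spec on the 8x8x4 grid with the reduced hub set."""
    kw.setdefault("grid_dims", (8, 8, 4))
    kw.setdefault("hub_table", synthetic_hub_table(4, 4, (8, 8, 4), 3.0))
    return CohortSpec(**kw)
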
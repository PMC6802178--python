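import numpy as np
import pytest

from ivfqol.ivf_integration import MonocularField, Reliability
from ivfqol.vf_geometry import generate_grid


@pytest.fixture(scope="session")
def grid_10_2():
    return generate_grid("10-2")


@pytest.fixture(scope="session")
def grid_24_2_right():
    return generate_grid("24-2", "right")


@pytest.fixture(scope="session")
def grid_24_2_left():
    return generate_grid("24-2", "left")


def make_field(grid, td, patient="P0", eye="OD", date="2006-01-01",
               md=-20.0, rel=None):
    return MonocularField(patient, eye, date, grid, np.asarray(td, float),
                          rel or Reliability(), md)


@pytest.fixture
def random_field_pair(grid_10_2):
    """Factory: seeded pair of 10-2 monocular fields for one patient."""

    def _make(seed):
        rng = np.random.default_rng(seed)
        td_od = rng.uniform(-35, 5, size=len(grid_10_2))
        td_os = rng.uniform(-35, 5, size=len(grid_10_2))
        return (make_field(grid_10_2, td_od, eye="OD"),
                make_field(grid_10_2, td_os, eye="OS"))

    return _make
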
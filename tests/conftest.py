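import numpy as np
import pytest

import vaxopt as v
from vaxopt.simulator import IMMUNE_CLASSES


@pytest.fixture(scope="session")
def monthu_grid():
    """The canonical 400-day Monday/Thursday grid (114 admissible slots)."""
    return v.make_time_grid(400, 24, [v.schedule.MONDAY, v.schedule.THURSDAY])


@pytest.fixture(scope="session")
def toy_grid():
    """A 20-day Mon/Thu grid matched to the toy simulator horizon."""
    return v.make_time_grid(20, 24, [v.schedule.MONDAY, v.schedule.THURSDAY])


@pytest.fixture(scope="session")
def toy_params():
    """Small, fast simulator configuration: 16x16 lattice, 20 days."""
    return v.SimParams(lattice_side=16, horizon_steps=60,
                       baseline_counts={c: 15 for c in IMMUNE_CLASSES},
                       vaccine_dose=15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
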
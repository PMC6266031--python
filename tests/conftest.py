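import numpy as np
import pytest

from ionpb import (synthesize_carbon_database, synthesize_proton_database)
from ionpb.geometry import make_phantom


@pytest.fixture(scope="session")
def proton_db():
    return synthesize_proton_database([150.0], depth_step=0.5, seed=1)


@pytest.fixture(scope="session")
def proton_db_multi():
    return synthesize_proton_database([130.0, 140.0, 150.0, 160.0],
                                      depth_step=0.5, seed=1)


@pytest.fixture(scope="session")
def carbon_db():
    return synthesize_carbon_database([280.0], depth_step=0.5, seed=2)


@pytest.fixture(scope="session")
def water_tank():
    grid, rois = make_phantom("water_tank", size=(100.0, 100.0, 200.0),
                              spacing=(2.0, 2.0, 2.0))
    return grid, rois


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
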
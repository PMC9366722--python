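import numpy as np
import pytest

from thermoqtl import simulate as sim
from thermoqtl.thermal import CameraCalibration


@pytest.fixture(scope="session")
def small_map():
    return sim.simulate_genetic_map(3, 60.0, 5, seed=11)


@pytest.fixture(scope="session")
def study_map():
    """12-chromosome, 156-marker map resembling a tomato SNP linkage map."""
    return sim.simulate_genetic_map(12, 80.0, 13, seed=1)


@pytest.fixture(scope="session")
def bc2s3(study_map):
    """160-line BC2S3 population on the study map."""
    return sim.simulate_ibc_population(study_map, 160, 2, 3, seed=2)


@pytest.fixture(scope="session")
def calib():
    return CameraCalibration()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
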
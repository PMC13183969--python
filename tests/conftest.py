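import numpy as np
import pytest

from nirtwin import experiments as ex
from nirtwin import optode
from nirtwin.sensor import SensorSpec


@pytest.fixture(scope="session")
def full_grid():
    return optode.build_grid(3, 11, 30.0)


@pytest.fixture(scope="session")
def full_cmap(full_grid):
    return optode.enumerate_channels(full_grid)


@pytest.fixture(scope="session")
def full_schedule(full_grid):
    return optode.build_tdm_schedule(full_grid, 4, 25.0, 25.0)


@pytest.fixture(scope="session")
def grid33():
    return optode.build_grid(3, 3, 30.0)


@pytest.fixture(scope="session")
def cmap33(grid33):
    return optode.enumerate_channels(grid33)


@pytest.fixture
def small_rig():
    """3x3 grid on a 256-px sensor: fast but runs the full noisy chain."""
    sensor = ex.experiment_sensor(width=256, height=256)
    return ex.default_rig(3, 3, 30.0, sensor=sensor, spot_radius_px=10)


@pytest.fixture
def noiseless_rig():
    sensor = ex.experiment_sensor(width=256, height=256, read_noise_e=0.0,
                                  shot_noise=False, quantize=False)
    return ex.default_rig(3, 3, 30.0, sensor=sensor, spot_radius_px=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
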
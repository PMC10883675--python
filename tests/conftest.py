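import numpy as np
import pytest

from cortiphos import (DynamicsParams, GeometryParams, RunConfig,
                       WedgeDipoleParams, make_grid_layout)


@pytest.fixture
def map_params():
    return WedgeDipoleParams()


@pytest.fixture
def dynamics():
    return DynamicsParams()


@pytest.fixture
def geometry():
    return GeometryParams()


@pytest.fixture
def small_run():
    return RunConfig(resolution=(64, 64), fov=16.0, dt=1.0 / 30.0, seed=3)


@pytest.fixture
def small_grid(map_params):
    """3x3 grid at mid-eccentric cortex, all points admissible."""
    return make_grid_layout(3, 3, 0.4, origin=14 + 0j, params=map_params)


def stim_array(n_frames, n_electrodes, amplitude_uA, pulse_width_us=170.0,
               frequency_hz=300.0):
    """Dense user-unit stimulation array with constant parameters."""
    stim = np.zeros((n_frames, n_electrodes, 3))
    stim[:, :, 0] = amplitude_uA
    stim[:, :, 1] = pulse_width_us
    stim[:, :, 2] = frequency_hz
    return stim
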
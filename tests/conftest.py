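import numpy as np
import pytest

from widefield_track3d.config import OpticalConfig, default_bead_classes
from widefield_track3d.fixtures import mini_library
from widefield_track3d.simulate import build_calibration_library


@pytest.fixture(scope="session")
def beads():
    return default_bead_classes()

@pytest.fixture(scope="session")
def small_bead(beads):
    return beads[0]

@pytest.fixture(scope="session")
def big_bead(beads):
    return beads[1]


@pytest.fixture(scope="session")
def mini_lib():
    """Two-class library on z in [-2, 2] at 0.5 um steps (16 patches)."""
    return mini_library(seed=7)


@pytest.fixture(scope="session")
def midi_lib():
    """Two-class library on z in [-5, 5] at 0.25 um steps (80 patches)."""
    optical = OpticalConfig(z_min_um=-5.0, z_max_um=5.0, z_step_um=0.25, seed=7)
    return build_calibration_library(default_bead_classes(), optical)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
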
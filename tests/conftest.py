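import numpy as np
import pytest

from ofvplan.controller import ControllerConfig, run_controller
from ofvplan.phantom import (PhantomConfig, build_beamset, compute_influence,
                             generate_phantom)

SMALL_CONFIG = PhantomConfig(grid_shape=(64, 64), spacing_mm=5.0)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_CONFIG, seed=3)


@pytest.fixture(scope="session")
def small_beamset(small_phantom):
    return build_beamset(small_phantom, n_angles=14, beamlets_per_angle=12)


@pytest.fixture(scope="session")
def small_influence(small_phantom, small_beamset):
    return compute_influence(small_phantom, small_beamset)


@pytest.fixture(scope="session")
def small_run(small_phantom, small_beamset, small_influence):
    """Full controller run on the fast 64x64 phantom."""
    plan, log = run_controller(small_phantom, small_beamset,
                               ControllerConfig(), influence=small_influence)
    return plan, log


@pytest.fixture(scope="session")
def default_phantom():
    """The default study phantom: 128x128 grid, 2.5 mm voxels, seed 7."""
    return generate_phantom(PhantomConfig(), seed=7)


@pytest.fixture(scope="session")
def default_beamset(default_phantom):
    return build_beamset(default_phantom)


@pytest.fixture(scope="session")
def default_influence(default_phantom, default_beamset):
    return compute_influence(default_phantom, default_beamset)


@pytest.fixture(scope="session")
def default_run(default_phantom, default_beamset, default_influence):
    """Full controller run at study scale (128x128, 28 angles, seed 7)."""
    plan, log = run_controller(default_phantom, default_beamset,
                               ControllerConfig(),
                               influence=default_influence)
    return plan, log
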
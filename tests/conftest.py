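import numpy as np
import pytest

from gatedspect import acquisition as acq
from gatedspect import kinetics, phantom


@pytest.fixture(scope="session")
def desk_config():
    return phantom.PhantomConfig()


@pytest.fixture(scope="session")
def coarse_config():
    """A coarse 8.8 mm grid with the same physical geometry, for fast tests."""
    return phantom.PhantomConfig(grid_dims=(48, 32, 28), voxel_size=8.8)


@pytest.fixture(scope="session")
def desk_sequence(desk_config):
    return phantom.generate_sequence(desk_config)


@pytest.fixture(scope="session")
def desk_by_gate(desk_sequence):
    return phantom.states_by_gate(desk_sequence)


@pytest.fixture(scope="session")
def tacset_case1(desk_by_gate):
    ref = desk_by_gate[(1, 1)]
    vols = phantom.tissue_volumes_ml(ref.labels, ref.voxel_size)
    return kinetics.assemble_tacset(1, tissue_volumes=vols)


@pytest.fixture(scope="session")
def small_detector():
    """Small-volume detector for operator tests."""
    return acq.DetectorModel(n_bins=(24, 16), sensitivity_scale=1.0, scatter_fraction=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
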
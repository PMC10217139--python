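import numpy as np
import pytest

from gliavasc.core_io import TWO_PHOTON_VOXEL, VoxelSize
from gliavasc.synthetic import SynthParams, generate_stack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230412)


@pytest.fixture(scope="session")
def two_photon_voxel() -> VoxelSize:
    return TWO_PHOTON_VOXEL


@pytest.fixture(scope="session")
def contact_stack():
    """One mid-size synthetic stack with endfeet and an AQP4 shell."""
    params = SynthParams(
        shape=(64, 256, 256),
        n_cells=4,
        coverage_fraction=0.15,
        aqp4_surface_fraction=0.2,
        seed=11,
    )
    return generate_stack(params)


@pytest.fixture(scope="session")
def soma_stack():
    """Synthetic stack tuned for soma volumetry (no endfeet)."""
    params = SynthParams(shape=(64, 256, 256), n_cells=4, seed=7)
    return generate_stack(params)


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """Random occupied 256-bin histogram with at least two occupied bins."""
    n_occ = int(rng.integers(2, 256))
    bins = rng.choice(256, size=n_occ, replace=False)
    counts = np.zeros(256, dtype=np.int64)
    counts[bins] = rng.integers(1, 1000, size=n_occ)
    return counts
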
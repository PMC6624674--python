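import numpy as np
import pytest

from dilagree.grids import BinaryMask, ImageGeometry
from dilagree.synthetic import SyntheticConfig, generate_cohort


def cube_mask(geometry: ImageGeometry, lo, hi) -> BinaryMask:
    """Axis-aligned solid cube of true voxels with index corners [lo, hi)."""
    vox = np.zeros(geometry.shape, dtype=bool)
    vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return BinaryMask(geometry=geometry, voxels=vox)


def random_mask(geometry: ImageGeometry, rng, p=0.25) -> BinaryMask:
    """Random non-empty mask (resampled until at least one voxel is set)."""
    while True:
        vox = rng.random(geometry.shape) < p
        if vox.any():
            return BinaryMask(geometry=geometry, voxels=vox)


@pytest.fixture(scope="session")
def unit_geom():
    return ImageGeometry(shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def aniso_geom():
    return ImageGeometry(shape=(12, 12, 6), spacing=(0.5, 0.5, 3.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 12-patient synthetic cohort with a second observer.

    Session-scoped because generation dominates test runtime; tests must not
    mutate the cases.
    """
    config = SyntheticConfig(n_patients=12, seed=42, two_observers=True,
                             ktrans_unusable_fraction=3 / 12)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def cohort90():
    """Full-size default cohort (90 patients, 19 uninformative Ktrans).

    Expensive (~1 min); shared across recovery and exclusion tests.
    """
    config = SyntheticConfig(n_patients=90, seed=2025)
    return config, generate_cohort(config)
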
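import numpy as np
import pytest

import lesionmap as lm


@pytest.fixture(scope="session")
def default_config():
    return lm.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def effect_cohort(default_config):
    """Default 50-subject cohort with the implanted walk-speed effect."""
    cohort, truth = lm.make_cohort(default_config)
    return cohort, truth


@pytest.fixture(scope="session")
def default_tract(default_config):
    return lm.make_tract(default_config)


@pytest.fixture(scope="session")
def default_atlas(default_config):
    return lm.make_label_atlas(default_config)


def small_grid(shape=(8, 8, 6), voxel_mm=2.0):
    return lm.centered_affine(shape, voxel_mm)


def mask_grid(data, voxel_mm=2.0):
    data = np.asarray(data, dtype=np.uint8)
    return lm.VolumeGrid(data=data, affine=lm.centered_affine(data.shape, voxel_mm))


def random_mask(rng, shape=(8, 8, 6), p=0.3, voxel_mm=2.0):
    return mask_grid((rng.random(shape) < p).astype(np.uint8), voxel_mm)
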
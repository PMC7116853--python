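import numpy as np
import pytest

from jointseg import (ClassTaxonomy, make_class_weights,
                      make_training_weights)
from jointseg.phantom import (LesionParams, PhantomConfig, TissueLayout,
                              wmh_scenario)


@pytest.fixture
def taxonomy() -> ClassTaxonomy:
    """Four tissue classes, one lesion class (the phantom default)."""
    return ClassTaxonomy(tissue_classes=(1, 2, 3, 4), lesion_classes=(5,))


@pytest.fixture
def weights(taxonomy):
    return make_class_weights(taxonomy)


@pytest.fixture
def training_weights(taxonomy):
    return make_training_weights(taxonomy)


def random_simplex(rng: np.random.Generator, n_classes: int,
                   n_voxels: int) -> np.ndarray:
    """Random per-voxel probability map of shape (C, N)."""
    g = rng.gamma(1.0, 1.0, size=(n_classes, n_voxels))
    return g / g.sum(axis=0, keepdims=True)


def random_labels(rng: np.random.Generator, taxonomy: ClassTaxonomy,
                  shape) -> np.ndarray:
    return rng.choice(np.array(taxonomy.all_classes), size=shape)


@pytest.fixture
def small_phantom_config() -> PhantomConfig:
    """32×32 phantom sized for fast training tests."""
    return wmh_scenario(
        seed=11, grid_shape=(32, 32),
        tissue_layout=TissueLayout(center_jitter=0.5),
        lesion_params=LesionParams(count_range=(1, 2),
                                   radius_range=(1.5, 3.0)))
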
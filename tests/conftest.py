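import numpy as np
import pytest

from glomquant.synth_imaging import (
    NOISELESS,
    FilamentSet,
    OpticsNoiseModel,
    RenderParams,
    VoxelGrid,
    make_scene,
)


@pytest.fixture(scope="session")
def thin_grid():
    """Co-localisation-style thin stack (3-4 z planes, ~1.1 µm depth)."""
    return VoxelGrid(shape_zyx=(4, 300, 300))


@pytest.fixture(scope="session")
def clean_scene(thin_grid):
    """Small noiseless scene without distractors, with ground truth."""
    return make_scene(
        thin_grid,
        n_branches=1,
        target_length=30.0,
        density=0.2,
        coloc_fraction=0.5,
        optics=NOISELESS,
        params=RenderParams(distractor_density_per_um3=0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_scene(thin_grid):
    """Same geometry at the generator's default optics settings."""
    return make_scene(
        thin_grid,
        n_branches=1,
        target_length=30.0,
        density=0.2,
        coloc_fraction=0.5,
        optics=OpticsNoiseModel(seed=3),
        seed=11,
    )


@pytest.fixture
def straight_filament():
    return FilamentSet([np.array([[1.0, 5.0, 0.555], [9.0, 5.0, 0.555]])], cell_id="cellX")
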
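import numpy as np
import pytest

from golgiatlas import EnzymeProfile, SceneConfig, render_cell


# Small grids keep simulated-cell tests fast on one CPU; the physical voxel
# size matches the acquisition geometry (0.2 um axial, 0.1 um lateral).
SMALL_GRID = (32, 64, 64)
SPACING = (0.2, 0.1, 0.1)


@pytest.fixture(scope="session")
def small_scene_cfg():
    return SceneConfig(grid_shape=SMALL_GRID, spacing=SPACING, n_ministacks=6, seed=7)


@pytest.fixture(scope="session")
def offset_scene(small_scene_cfg):
    """One rendered dual-channel cell with a 0.5-um axial offset."""
    return render_cell(
        small_scene_cfg,
        (EnzymeProfile("near", 0.0), EnzymeProfile("far", 0.5)),
    )


@pytest.fixture(scope="session")
def self_pair_scene(small_scene_cfg):
    """Dual-label control: same axial profile in both channels."""
    return render_cell(
        small_scene_cfg,
        (EnzymeProfile("ctrl_a", 0.2), EnzymeProfile("ctrl_b", 0.2)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
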
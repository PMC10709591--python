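import numpy as np
import pytest

from vtsct.grid import VolumeGrid, empty_like_template
from vtsct.phantom import NoduleSpec, NoduleType, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def iso05_template():
    """0.5 mm isotropic 64^3 grid centred on the origin."""
    return empty_like_template(
        (64, 64, 64), (0.5, 0.5, 0.5), (-15.75, -15.75, -15.75)
    )


@pytest.fixture
def solid_sphere_20mm(iso05_template):
    """Noise-free 20 mm solid sphere on the 0.5 mm grid."""
    spec = NoduleSpec(
        NoduleType.SOLID, 20.0, 20.0, (0.0, 0.0, 0.0), noise_sd_hu=0.0
    )
    vol, truth = generate_phantom(spec, iso05_template, seed=7)
    return vol, truth


@pytest.fixture
def part_solid_1mm():
    """Noisy part-solid nodule (total 30, solid 18) on a 1 mm grid."""
    grid = empty_like_template((40, 40, 40), (1.0, 1.0, 1.0), (-19.5, -19.5, -19.5))
    spec = NoduleSpec(
        NoduleType.PART_SOLID, 30.0, 18.0, (0.0, 0.0, 0.0), noise_sd_hu=20.0
    )
    vol, truth = generate_phantom(spec, grid, seed=11)
    return vol, truth


@pytest.fixture
def ramp_volume():
    """Volume whose HU is a pure linear function of z."""
    nz = 40
    z = np.arange(nz, dtype=np.float32)
    vox = np.broadcast_to(-800.0 + 5.0 * z, (8, 8, nz)).copy()
    return VolumeGrid(vox, (1.0, 1.0, 1.0))
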
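"""Shared fixtures: phantoms and synthetic specimens, generated once."""

import numpy as np
import pytest

from trabmorph import VoxelVolume, make_phantom, make_synthetic_metacarpal
from trabmorph.synthetic import PhantomSpec


@pytest.fixture(scope="session")
def plate_phantom():
    """Plate phantom t=0.25 mm, p=1.0 mm, voxel 0.025 mm, normal axis 0."""
    spec = PhantomSpec(kind="plate", voxel_size=0.025, dims=(120, 120, 120),
                       thickness=0.25, period=1.0, axis=(1.0, 0.0, 0.0))
    vol, truth = make_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def foam_phantom():
    spec = PhantomSpec(kind="sphere_foam", voxel_size=0.05, dims=(64, 64, 64),
                       target_bvtv=0.3, seed=7)
    vol, truth = make_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def adult_specimen():
    """Fused adult synthetic metacarpal (epiphysis present, no gap)."""
    return make_synthetic_metacarpal(200.0, seed=1)


@pytest.fixture(scope="session")
def juvenile_specimen():
    """Unfused specimen with an ossified epiphysis and growth-plate gap."""
    sp = make_synthetic_metacarpal(100.0, seed=7)
    assert sp.epiphysis_present and sp.gap_center is not None
    return sp


@pytest.fixture(scope="session")
def neonate_specimen():
    return make_synthetic_metacarpal(4.0, seed=3)


@pytest.fixture()
def solid_cube_mask():
    """10 mm solid cubic mask at 0.1 mm voxels."""
    return VoxelVolume(np.ones((101, 101, 101), np.uint8), 0.1)


def full_mask(vol: VoxelVolume) -> VoxelVolume:
    return vol.like(np.ones(vol.shape, np.uint8))
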
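"""Shared fixtures: tiny deterministic instances for unit/property tests."""

import numpy as np
import pytest
from scipy import ndimage

from ybremdose.phantoms import PhantomConfig, make_virtual_patient
from ybremdose.projector import CDRModel, ProjectionGeometry
from ybremdose.volumes import VoxelGrid, VoxelVolume


@pytest.fixture(scope="session")
def tiny_grid() -> VoxelGrid:
    return VoxelGrid((16, 16, 8), (4.8, 4.8, 4.8))


@pytest.fixture(scope="session")
def tiny_geom() -> ProjectionGeometry:
    return ProjectionGeometry(n_views=16, n_bins_u=16, n_bins_v=8, radius_mm=60.0)


@pytest.fixture(scope="session")
def tiny_cdr() -> CDRModel:
    return CDRModel(c0_mm=2.0, c1=0.05)


@pytest.fixture(scope="session")
def smooth_phantom(tiny_grid) -> VoxelVolume:
    """Smooth two-lesion activity distribution on the tiny grid."""
    x = np.zeros(tiny_grid.shape)
    x[4:9, 4:9, 2:6] = 2.0
    x[10:13, 8:12, 3:6] = 5.0
    return VoxelVolume(tiny_grid, ndimage.gaussian_filter(x, 1.2), "activity_MBq")


@pytest.fixture(scope="session")
def tiny_mu(tiny_grid) -> VoxelVolume:
    return VoxelVolume(tiny_grid, np.full(tiny_grid.shape, 0.015), "attenuation_per_cm")


@pytest.fixture(scope="session")
def desk_patient():
    """One desk-scale virtual patient (shared, read-only)."""
    return make_virtual_patient(PhantomConfig(seed=42))
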
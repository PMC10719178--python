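"""Synthetic virtual-patient phantoms for 90Y radioembolization studies.

Generates co-registered activity (MBq per voxel) and density (g/cm^3) volumes
with VOI masks: an ellipsoid-union liver containing ellipsoidal lesions at
requested mL volumes, lungs, a spine insert and a soft-tissue body.  Liver
activity is a base concentration times a lesion uptake ratio times a
multiplicative log-normal texture field (uniform activity is known to train
dose networks poorly, so the texture is on by default).  A torso-phantom
preset mirrors a physical liver/lung/spine phantom with three hot inserts.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import VoxelGrid, VoxelVolume, VOISet

# Compartment densities, g/cm^3 (torso-phantom-like values).
DENSITY_AIR = 0.0012
DENSITY_LUNG = 0.30
DENSITY_SOFT_TISSUE = 1.00
DENSITY_BONE = 1.40

# Grid presets.  Desk scale keeps Monte Carlo and training in minutes; the
# full-scale preset matches clinical CT sampling.
DESK_GRID = VoxelGrid((128, 128, 64), (2.0, 2.0, 2.0))
FULL_GRID = VoxelGrid((512, 512, 194), (0.98, 0.98, 2.0))


@dataclass
class PhantomConfig:
    seed: int = 0
    grid: VoxelGrid = field(default_factory=lambda: DESK_GRID)
    liver_volume_mL: float = 1500.0
    lesion_volumes_mL: list[float] = field(default_factory=lambda: [29.6, 27.4, 21.0, 5.7])
    lesion_uptake_ratios: list[float] = field(default_factory=lambda: [4.0, 3.0, 5.0, 6.0])
    texture_sigma: float = 0.35
    texture_corr_mm: float = 12.0
    lung_density: float = DENSITY_LUNG
    soft_tissue_density: float = DENSITY_SOFT_TISSUE
    bone_density: float = DENSITY_BONE
    total_activity_GBq: float = 2.0

    def __post_init__(self) -> None:
        if len(self.lesion_volumes_mL) != len(self.lesion_uptake_ratios):
            raise ValueError("one uptake ratio per lesion volume is required")
        if any(v <= 0 for v in self.lesion_volumes_mL):
            raise ValueError("lesion volumes must be > 0")
        if any(r <= 0 for r in self.lesion_uptake_ratios):
            raise ValueError("uptake ratios must be > 0")
        if self.texture_sigma < 0:
            raise ValueError("texture sigma must be >= 0")
        if self.liver_volume_mL <= 0 or self.total_activity_GBq < 0:
            raise ValueError("liver volume must be > 0 and activity >= 0")


# ---------------------------------------------------------------------------
# geometry helpers


def _center_grids_mm(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates relative to the grid centre, broadcastable."""
    cx, cy, cz = (0.5 * e for e in grid.extent_mm())
    x = grid.centers_mm(0) - grid.origin_mm[0] - cx
    y = grid.centers_mm(1) - grid.origin_mm[1] - cy
    z = grid.centers_mm(2) - grid.origin_mm[2] - cz
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _ellipsoid(grid: VoxelGrid, center_mm, semiaxes_mm) -> np.ndarray:
    x, y, z = _center_grids_mm(grid)
    a, b, c = semiaxes_mm
    r2 = ((x - center_mm[0]) / a) ** 2 + ((y - center_mm[1]) / b) ** 2 + ((z - center_mm[2]) / c) ** 2
    return r2 <= 1.0


def _ellipsoid_r2(grid: VoxelGrid, center_mm, semiaxes_mm) -> np.ndarray:
    x, y, z = _center_grids_mm(grid)
    a, b, c = semiaxes_mm
    return ((x - center_mm[0]) / a) ** 2 + ((y - center_mm[1]) / b) ** 2 + ((z - center_mm[2]) / c) ** 2


def _exact_volume_blob(
    grid: VoxelGrid, center_mm, semiaxes_mm, volume_mL: float, within: np.ndarray
) -> np.ndarray:
    """Ellipsoidal mask of exactly round(volume / voxel volume) voxels.

    Takes the n voxels of smallest normalized ellipsoid radius inside
    ``within``, which pins the realized volume to the request within one
    voxel volume and guarantees containment.
    """
    n_vox = int(round(volume_mL / grid.voxel_volume_mL))
    if n_vox < 1:
        raise ValueError(f"requested volume {volume_mL} mL is below one voxel")
    if int(within.sum()) < n_vox:
        raise ValueError(
            f"requested {volume_mL} mL ({n_vox} voxels) exceeds available region "
            f"({int(within.sum())} voxels)"
        )
    r2 = _ellipsoid_r2(grid, center_mm, semiaxes_mm)
    r2 = np.where(within, r2, np.inf)
    flat = np.argpartition(r2.ravel(), n_vox - 1)[:n_vox]
    mask = np.zeros(grid.shape, dtype=bool)
    mask.ravel()[flat] = True
    return mask


def _texture_field(grid: VoxelGrid, sigma: float, corr_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative log-normal field: filtered white noise, exponentiated."""
    if sigma == 0.0:
        return np.ones(grid.shape)
    noise = rng.standard_normal(grid.shape)
    sig_vox = [max(corr_mm / s, 1e-6) / 2.355 for s in grid.voxel_size_mm]
    smooth = ndimage.gaussian_filter(noise, sig_vox, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    f = np.exp(sigma * smooth)
    return f / f.mean()


# ---------------------------------------------------------------------------
# virtual patient


def make_virtual_patient(config: PhantomConfig) -> tuple[VoxelVolume, VoxelVolume, VOISet]:
    """Generate one virtual patient: activity map, density map and VOIs.

    The liver is a union of one large and two smaller random ellipsoids in the
    right-upper abdomen; lesions are ellipsoids of exactly the requested
    volumes placed inside it.  Activity = base concentration x uptake ratio x
    log-normal texture inside the liver, zero outside (microspheres are
    trapped in the treated liver).  The map is globally rescaled so the total
    equals ``total_activity_GBq`` exactly.
    """
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    ex, ey, ez = grid.extent_mm()

    # Body: soft-tissue elliptic cylinder over the full axial extent.
    x, y, z = _center_grids_mm(grid)
    body = ((x / (0.45 * ex)) ** 2 + (y / (0.40 * ey)) ** 2) <= 1.0
    body = np.broadcast_to(body, grid.shape).copy()

    # Liver: union of ellipsoids, volume tuned by uniform radial scaling.
    lc = np.array([-0.15 * ex, -0.05 * ey, 0.10 * ez])
    lc += rng.uniform(-6.0, 6.0, size=3)
    base_axes = np.array([0.26 * ex, 0.24 * ey, 0.30 * ez])
    sub = []
    for _ in range(2):
        off = rng.uniform(-0.4, 0.4, size=3) * base_axes
        ax = base_axes * rng.uniform(0.45, 0.7, size=3)
        sub.append((lc + off, ax))

    def liver_at(scale: float) -> np.ndarray:
        m = _ellipsoid(grid, lc, base_axes * scale)
        for c, a in sub:
            m |= _ellipsoid(grid, c, a * scale)
        return m & body

    lo, hi = 0.3, 1.6
    target_vox = config.liver_volume_mL / grid.voxel_volume_mL
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if liver_at(mid).sum() < target_vox:
            lo = mid
        else:
            hi = mid
    liver = liver_at(hi)
    if liver.sum() < target_vox * 0.8:
        raise ValueError("grid too small to contain the requested liver volume")

    total_lesion = sum(config.lesion_volumes_mL)
    if total_lesion >= config.liver_volume_mL:
        raise ValueError(
            f"total lesion volume {total_lesion} mL exceeds liver volume "
            f"{config.liver_volume_mL} mL"
        )

    # Lesions: ellipsoids of exact voxel-count volume, disjoint, inside liver.
    interior = ndimage.binary_erosion(liver, iterations=2)
    cand = np.argwhere(interior if interior.any() else liver)
    lesions: list[np.ndarray] = []
    occupied = np.zeros(grid.shape, dtype=bool)
    for vol_mL in config.lesion_volumes_mL:
        r_eq = (3.0 * vol_mL * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        ratios = rng.uniform(0.7, 1.4, size=3)
        ratios /= np.prod(ratios) ** (1.0 / 3.0)
        axes = 1.3 * r_eq * ratios  # slack so the exact-volume cut stays ellipsoidal
        placed = None
        for _ in range(200):
            idx = cand[rng.integers(len(cand))]
            c = [
                grid.origin_mm[a] + (idx[a] + 0.5) * grid.voxel_size_mm[a]
                - grid.origin_mm[a] - 0.5 * grid.extent_mm()[a]
                for a in range(3)
            ]
            allowed = liver & ~occupied
            try:
                m = _exact_volume_blob(grid, c, axes, vol_mL, allowed)
            except ValueError:
                continue
            # reject fragmented placements (cut spilled far from the centre)
            if _ellipsoid_r2(grid, c, axes * 1.5)[m].max() <= 1.0:
                placed = m
                break
        if placed is None:
            raise ValueError(f"could not place a {vol_mL} mL lesion inside the liver")
        lesions.append(placed)
        occupied |= placed

    # Lungs: two ellipsoids in the upper-posterior body at lung density.
    lung_l = _ellipsoid(grid, (0.18 * ex, -0.12 * ey, 0.30 * ez), (0.13 * ex, 0.14 * ey, 0.22 * ez))
    lung_r = _ellipsoid(grid, (-0.18 * ex, -0.12 * ey, 0.34 * ez), (0.13 * ex, 0.14 * ey, 0.20 * ez))
    lungs = (lung_l | lung_r) & body & ~liver
    # Spine: posterior cylinder of bone density.
    spine = ((x / (0.05 * ex)) ** 2 + ((y - 0.28 * ey) / (0.05 * ey)) ** 2) <= 1.0
    bone = np.broadcast_to(spine, grid.shape) & body & ~liver & ~lungs

    density = np.full(grid.shape, DENSITY_AIR)
    density[body] = config.soft_tissue_density
    density[lungs] = config.lung_density
    density[bone] = config.bone_density

    uptake = np.zeros(grid.shape)
    uptake[liver] = 1.0
    for les, ratio in zip(lesions, config.lesion_uptake_ratios):
        uptake[les] = ratio
    texture = _texture_field(grid, config.texture_sigma, config.texture_corr_mm, rng)
    activity = uptake * texture
    s = activity.sum()
    if s > 0:
        activity *= (config.total_activity_GBq * 1000.0) / s  # MBq total, exact

    vois = VOISet(
        grid=grid,
        lesions=lesions,
        liver=liver,
        lungs=lungs,
        bone=bone,
        background=body & ~liver,
    )
    return (
        VoxelVolume(grid, activity, "activity_MBq"),
        VoxelVolume(grid, density, "density_g_per_cm3"),
        vois,
    )


# ---------------------------------------------------------------------------
# torso phantom preset


def make_torso_phantom(
    scale: float = 1.0,
    seed: int = 0,
    grid: VoxelGrid | None = None,
    total_activity_GBq: float = 2.0,
) -> tuple[VoxelVolume, VoxelVolume, VOISet]:
    """Simulated torso phantom: 1200 mL liver with 29/16/8 mL hot inserts.

    Uniform concentration per compartment: inserts in 6.4-7.8 MBq/mL and
    background liver 1.3 MBq/mL, then a single global factor brings the total
    to 2.0 GBq at ``scale`` = 1 (the insert-to-background ratios are
    unaffected).  ``scale`` multiplies the whole activity map, for desk-scale
    count levels.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    grid = grid or DESK_GRID
    rng = np.random.default_rng(seed)
    ex, ey, ez = grid.extent_mm()
    x, y, z = _center_grids_mm(grid)

    body = ((x / (0.46 * ex)) ** 2 + (y / (0.42 * ey)) ** 2) <= 1.0
    body = np.broadcast_to(body, grid.shape).copy()

    lc = np.array([-0.14 * ex, -0.04 * ey, 0.0])
    axes = np.array([0.28 * ex, 0.26 * ey, 0.30 * ez])

    def liver_at(s: float) -> np.ndarray:
        return _ellipsoid(grid, lc, axes * s) & body

    lo, hi = 0.2, 1.5
    target_vox = 1200.0 / grid.voxel_volume_mL
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if liver_at(mid).sum() < target_vox:
            lo = mid
        else:
            hi = mid
    liver = liver_at(hi)

    insert_specs = [  # (volume mL, concentration MBq/mL, offset fraction of liver axes)
        (29.0, 7.0, np.array([0.35, -0.2, 0.25])),
        (16.0, 6.5, np.array([-0.35, 0.25, -0.1])),
        (8.0, 7.8, np.array([0.1, 0.35, -0.4])),
    ]
    lesions = []
    occupied = np.zeros(grid.shape, dtype=bool)
    scaled_axes = axes * hi
    for vol_mL, _conc, off in insert_specs:
        c = lc + off * scaled_axes * 0.8
        r_eq = (3.0 * vol_mL * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        shape_ax = (1.3 * r_eq) * np.array([1.25, 0.9, 0.9]) if vol_mL == 29.0 else (1.3 * r_eq) * np.ones(3)
        m = _exact_volume_blob(grid, c, shape_ax, vol_mL, liver & ~occupied)
        lesions.append(m)
        occupied |= m

    lung_l = _ellipsoid(grid, (0.20 * ex, -0.10 * ey, 0.30 * ez), (0.13 * ex, 0.15 * ey, 0.22 * ez))
    lung_r = _ellipsoid(grid, (-0.20 * ex, -0.10 * ey, 0.32 * ez), (0.13 * ex, 0.15 * ey, 0.20 * ez))
    lungs = (lung_l | lung_r) & body & ~liver
    spine = ((x / (0.05 * ex)) ** 2 + ((y - 0.30 * ey) / (0.05 * ey)) ** 2) <= 1.0
    bone = np.broadcast_to(spine, grid.shape) & body & ~liver & ~lungs

    density = np.full(grid.shape, DENSITY_AIR)
    density[body] = DENSITY_SOFT_TISSUE
    density[lungs] = DENSITY_LUNG
    density[bone] = DENSITY_BONE

    conc = np.zeros(grid.shape)  # MBq/mL
    conc[liver] = 1.3
    for m, (_v, c_MBq_mL, _o) in zip(lesions, insert_specs):
        conc[m] = c_MBq_mL
    activity = conc * grid.voxel_volume_mL  # MBq per voxel
    s = activity.sum()
    if s > 0:
        activity *= (total_activity_GBq * 1000.0) / s
    activity *= scale
    del rng  # geometry is deterministic; kept for interface symmetry

    vois = VOISet(grid=grid, lesions=lesions, liver=liver, lungs=lungs, bone=bone,
                  background=body & ~liver)
    return (
        VoxelVolume(grid, activity, "activity_MBq"),
        VoxelVolume(grid, density, "density_g_per_cm3"),
        vois,
    )


# ---------------------------------------------------------------------------
# CT-to-density and density-to-attenuation

# Two-segment piecewise-linear HU -> g/cm^3 calibration (Schneider-type):
# air (-1000 HU) 0.0012, water (0 HU) 1.0, +1000 HU 1.60; linear continuation
# above +1000, clamped at the air density below -1000.
_HU_ANCHORS = np.array([-1000.0, 0.0, 1000.0])
_RHO_ANCHORS = np.array([DENSITY_AIR, 1.0, 1.60])


def ct_to_density(hu: VoxelVolume) -> VoxelVolume:
    v = hu.values
    if not np.all(np.isfinite(v)):
        raise ValueError("HU volume contains non-finite values")
    rho = np.interp(v, _HU_ANCHORS, _RHO_ANCHORS)
    high = v > _HU_ANCHORS[-1]
    slope_hi = (_RHO_ANCHORS[2] - _RHO_ANCHORS[1]) / (_HU_ANCHORS[2] - _HU_ANCHORS[1])
    rho[high] = _RHO_ANCHORS[-1] + slope_hi * (v[high] - _HU_ANCHORS[-1])
    return VoxelVolume(hu.grid, np.maximum(rho, 0.0), "density_g_per_cm3")


# NIST mass attenuation of liquid water, total with coherent, cm^2/g.
WATER_MU_RHO_ENERGY_KEV = np.array(
    [50, 60, 80, 100, 150, 200, 300, 400, 500, 600, 800, 1000, 1250, 1500, 2000, 3000],
    dtype=float,
)
WATER_MU_RHO_CM2_G = np.array(
    [0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186, 0.1061, 0.09687,
     0.08956, 0.07865, 0.07072, 0.06323, 0.05754, 0.04942, 0.03969]
)


def water_mass_attenuation(energy_keV: float | np.ndarray) -> np.ndarray:
    """Log-log interpolated water mu/rho (cm^2/g) on [50, 2300] keV."""
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e < 50.0) or np.any(e > 2300.0):
        raise ValueError("energy outside tabulated range 50-2300 keV")
    return np.exp(np.interp(np.log(e), np.log(WATER_MU_RHO_ENERGY_KEV), np.log(WATER_MU_RHO_CM2_G)))


def density_to_attenuation(density: VoxelVolume, energy_keV: float) -> VoxelVolume:
    """Linear attenuation map mu = rho * (mu/rho)_water(E), cm^-1."""
    mu_rho = float(water_mass_attenuation(energy_keV))
    return VoxelVolume(density.grid, density.values * mu_rho, "attenuation_per_cm")
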
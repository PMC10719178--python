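"""Voxel-grid containers shared by every stage of the pipeline.

All volumes (activity, density, attenuation, dose rate) live on axis-aligned
grids with physical voxel sizes in mm.  Activity volumes store *per-voxel*
activity in MBq (not concentration); density is g/cm^3; attenuation is cm^-1;
dose rate is nGy/s.  Masks are boolean arrays on the same grid, 0-based,
half-open voxel indexing, and every volume of a study shares one world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

QUANTITIES = (
    "activity_MBq",
    "density_g_per_cm3",
    "attenuation_per_cm",
    "dose_rate_nGy_per_s",
    "hounsfield",
    "dose_Gy",
)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: shape, voxel pitch (mm) and world origin (mm).

    The world position of voxel centre (i, j, k) is
    ``origin_mm + (i + 0.5, j + 0.5, k + 0.5) * voxel_size_mm``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_size_mm
        return sx * sy * sz

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.voxel_size_mm[axis]

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_mm))


@dataclass
class VoxelVolume:
    """A scalar field on a :class:`VoxelGrid` with a declared physical quantity."""

    grid: VoxelGrid
    values: np.ndarray
    quantity: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.quantity in ("activity_MBq", "density_g_per_cm3") and self.values.min() < 0:
            raise ValueError(f"{self.quantity} values must be >= 0")

    def copy(self, values: np.ndarray | None = None, quantity: str | None = None) -> "VoxelVolume":
        return VoxelVolume(
            grid=self.grid,
            values=self.values.copy() if values is None else values,
            quantity=self.quantity if quantity is None else quantity,
        )

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class VOISet:
    """Named boolean masks on one grid.

    ``healthy_liver`` is derived: liver minus the union of lesions.  The same
    convention the evaluation metrics use ("treated liver minus the lesions").
    """

    grid: VoxelGrid
    lesions: list[np.ndarray] = field(default_factory=list)
    liver: np.ndarray | None = None
    lungs: np.ndarray | None = None
    bone: np.ndarray | None = None
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("liver", "lungs", "bone", "background"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.grid.shape:
                    raise ValueError(f"mask {name} shape {m.shape} != grid {self.grid.shape}")
                setattr(self, name, m)
        self.lesions = [np.asarray(m, dtype=bool) for m in self.lesions]
        for m in self.lesions:
            if m.shape != self.grid.shape:
                raise ValueError("lesion mask shape mismatch")

    @property
    def healthy_liver(self) -> np.ndarray:
        if self.liver is None:
            raise ValueError("VOISet has no liver mask")
        out = self.liver.copy()
        for les in self.lesions:
            out &= ~les
        return out

    def lesion_union(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for les in self.lesions:
            out |= les
        return out

    def mask_volume_mL(self, mask: np.ndarray) -> float:
        return float(mask.sum()) * self.grid.voxel_volume_mL


# ---------------------------------------------------------------------------
# NIfTI-1 round trip


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size_mm) + [1.0])
    aff[:3, 3] = np.asarray(grid.origin_mm) + 0.5 * np.asarray(grid.voxel_size_mm)
    return aff


def _grid_from_img(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3] - 0.5 * np.asarray(zooms)
    return VoxelGrid(
        shape=tuple(int(n) for n in img.shape[:3]),
        voxel_size_mm=tuple(float(z) for z in zooms),
        origin_mm=tuple(float(o) for o in origin),
    )


def save_volume(vol: VoxelVolume, path: str) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.grid))
    img.header["descrip"] = vol.quantity.encode()[:79]
    nib.save(img, path)


def load_volume(path: str, quantity: str | None = None) -> VoxelVolume:
    img = nib.load(path)
    q = quantity or img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "activity_MBq"
    return VoxelVolume(grid=_grid_from_img(img), values=np.asarray(img.dataobj, dtype=np.float64), quantity=q)


# Integer label convention for VOI export: 0 background-air, 1 body background,
# 2 liver (healthy), 3 lungs, 4 bone, 10+i lesion i.
def save_voiset(vois: VOISet, path: str) -> None:
    lab = np.zeros(vois.grid.shape, dtype=np.int16)
    if vois.background is not None:
        lab[vois.background] = 1
    if vois.liver is not None:
        lab[vois.liver] = 2
    if vois.lungs is not None:
        lab[vois.lungs] = 3
    if vois.bone is not None:
        lab[vois.bone] = 4
    for i, les in enumerate(vois.lesions):
        lab[les] = 10 + i
    img = nib.Nifti1Image(lab, _affine(vois.grid))
    nib.save(img, path)


def load_voiset(path: str) -> VOISet:
    img = nib.load(path)
    lab = np.asarray(img.dataobj).astype(np.int16)
    grid = _grid_from_img(img)
    lesion_ids = sorted(int(v) for v in np.unique(lab) if v >= 10)
    lesions = [lab == i for i in lesion_ids]
    liver = (lab == 2) | np.any(lesions, axis=0) if lesions else (lab == 2)
    return VOISet(
        grid=grid,
        lesions=lesions,
        liver=liver,
        lungs=(lab == 3),
        bone=(lab == 4),
        background=(lab == 1),
    )
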
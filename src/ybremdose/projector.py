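"""Deterministic SPECT system model A for parallel-hole bremsstrahlung imaging.

Rotation-based projector: for each view the volume is rotated into the
detector frame, attenuated along the ray axis, blurred per depth plane with a
distance-dependent Gaussian (collimator-detector response, CDR), and summed
along rays.  The rotation is a sparse bilinear *splat* matrix, so the adjoint
used by OS-EM is literally the transposed matrix and the projector/
backprojector pair satisfies <Ax, p> = <x, A^T p> to machine precision.

Conventions
-----------
Volume axes are (x, y, z) with nx == ny (square in-plane grid).  At view
angle 0 the detector sits on the +y side with rays along +y; detector bin u
maps to x and v to z.  View angles increase counter-clockwise over 360 deg.
The grid's in-plane voxel pitch must equal the detector bin pitch (no silent
resampling).  Activity is per-voxel (MBq), so with mu = 0, CDR off and unit
efficiency each view's bin sum equals the total activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage, sparse

from .volumes import VoxelVolume


@dataclass(frozen=True)
class ProjectionGeometry:
    n_views: int = 128
    n_bins_u: int = 128
    n_bins_v: int = 80
    pitch_mm: tuple[float, float] = (4.8, 4.8)
    radius_mm: float = 250.0
    energy_window_keV: tuple[float, float] = (105.0, 195.0)

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_bins_u < 1 or self.n_bins_v < 1:
            raise ValueError("view/bin counts must be >= 1")
        if any(p <= 0 for p in self.pitch_mm):
            raise ValueError("bin pitches must be > 0")
        if self.energy_window_keV[0] >= self.energy_window_keV[1]:
            raise ValueError("energy window lower bound must be below upper bound")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * (360.0 / self.n_views)


@dataclass
class ProjectionSet:
    geometry: ProjectionGeometry
    values: np.ndarray  # (n_views, n_bins_u, n_bins_v)
    kind: str  # mean_primary | mean_scatter | noisy_counts | attenuation_line_integral

    KINDS = ("mean_primary", "mean_scatter", "noisy_counts", "attenuation_line_integral")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expect = (self.geometry.n_views, self.geometry.n_bins_u, self.geometry.n_bins_v)
        if self.values.shape != expect:
            raise ValueError(f"projection shape {self.values.shape} != {expect}")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("projection values must be finite and >= 0")
        if self.kind == "noisy_counts" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("noisy_counts must be integer-valued")

    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class CDRModel:
    """Depth-dependent Gaussian response: fwhm(d) = c0 + c1 * d, in mm."""

    c0_mm: float = 2.0
    c1: float = 0.05
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.c0_mm < 0 or self.c1 < 0:
            raise ValueError("CDR coefficients must be >= 0")

    @classmethod
    def off(cls) -> "CDRModel":
        return cls(0.0, 0.0, enabled=False)

    def sigma_mm(self, distance_mm: np.ndarray) -> np.ndarray:
        fwhm = self.c0_mm + self.c1 * np.maximum(distance_mm, 0.0)
        return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# cached sparse rotation operators

_ROT_CACHE: dict[tuple, tuple[sparse.csr_matrix, sparse.csr_matrix, sparse.csr_matrix]] = {}


def _rotation_ops(n: int, pitch: float, angle_deg: float):
    """(splat, splat^T, value-gather) sparse ops for one in-plane rotation.

    ``splat`` deposits each input voxel into the rotated frame with bilinear
    weights (mass preserving: every interior voxel's weights sum to 1).  The
    value-gather variant is the row-normalised splat, used for the
    attenuation map where values rather than mass should be interpolated.
    """
    key = (n, round(pitch, 9), round(angle_deg % 360.0, 9))
    hit = _ROT_CACHE.get(key)
    if hit is not None:
        return hit
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    idx = (np.arange(n) + 0.5 - n / 2.0) * pitch
    X, Y = np.meshgrid(idx, idx, indexing="ij")
    # detector frame coords: rotate world by -angle
    xr = c * X + s * Y
    yr = -s * X + c * Y
    fx = xr / pitch + n / 2.0 - 0.5
    fy = yr / pitch + n / 2.0 - 0.5
    i0 = np.floor(fx).astype(np.int64)
    j0 = np.floor(fy).astype(np.int64)
    wx = fx - i0
    wy = fy - j0
    src = np.arange(n * n)
    rows, cols, vals = [], [], []
    for di, wxi in ((0, 1.0 - wx), (1, wx)):
        for dj, wyj in ((0, 1.0 - wy), (1, wy)):
            ii = i0 + di
            jj = j0 + dj
            ok = (ii >= 0) & (ii < n) & (jj >= 0) & (jj < n)
            w = (wxi * wyj).ravel()
            okf = ok.ravel() & (w > 0)
            rows.append((ii * n + jj).ravel()[okf])
            cols.append(src[okf])
            vals.append(w[okf])
    M = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    ).tocsr()
    rowsum = np.asarray(M.sum(axis=1)).ravel()
    inv = np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1e-300), 0.0)
    Mg = sparse.diags(inv) @ M
    out = (M, M.T.tocsr(), Mg.tocsr())
    _ROT_CACHE[key] = out
    return out


def _check_compat(x: VoxelVolume, geom: ProjectionGeometry) -> None:
    nx, ny, nz = x.grid.shape
    sx, sy, sz = x.grid.voxel_size_mm
    if nx != ny or abs(sx - sy) > 1e-9:
        raise ValueError("projector requires a square in-plane grid (nx == ny, sx == sy)")
    if nx != geom.n_bins_u or nz != geom.n_bins_v:
        raise ValueError(
            f"grid ({nx},{ny},{nz}) does not match detector bins "
            f"({geom.n_bins_u},{geom.n_bins_v}); resample first"
        )
    if abs(sx - geom.pitch_mm[0]) > 1e-9 or abs(sz - geom.pitch_mm[1]) > 1e-9:
        raise ValueError(
            f"grid pitch ({sx},{sz}) mm does not match bin pitch {geom.pitch_mm}; "
            "resample first"
        )


def _attenuation_weights(mur: np.ndarray, dy_mm: float) -> np.ndarray:
    """Per-voxel survival e^(-int mu dl) toward the detector at the +y side.

    The path integral counts full planes strictly between the voxel and the
    detector plus half the voxel's own plane (midpoint rule).
    """
    dy_cm = dy_mm / 10.0
    rev = np.cumsum(mur[:, ::-1, :], axis=1)[:, ::-1, :]  # inclusive sum from voxel to edge
    path = (rev - 0.5 * mur) * dy_cm
    return np.exp(-path)


def _plane_sigmas(geom: ProjectionGeometry, ny: int, dy_mm: float, cdr: CDRModel) -> np.ndarray:
    yc = (np.arange(ny) + 0.5 - ny / 2.0) * dy_mm
    return cdr.sigma_mm(geom.radius_mm - yc)


def project(
    x: VoxelVolume,
    mu: VoxelVolume | None,
    geom: ProjectionGeometry,
    cdr: CDRModel | None = None,
    efficiency: float = 1.0,
    views: np.ndarray | None = None,
) -> ProjectionSet:
    """Forward project an activity volume into mean projections (linear in x).

    With ``views`` given, only those views are computed (others stay zero).
    """
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    cdr = cdr or CDRModel.off()
    _check_compat(x, geom)
    if mu is not None and mu.grid != x.grid:
        raise ValueError("activity and attenuation must share one grid")
    n, _ny, nz = x.grid.shape
    sy = x.grid.voxel_size_mm[1]
    sigmas = _plane_sigmas(geom, n, sy, cdr) if cdr.enabled else None
    vol2 = x.values.reshape(n * n, nz)
    mu2 = mu.values.reshape(n * n, nz) if mu is not None else None
    out = np.zeros((geom.n_views, n, nz))
    view_ids = range(geom.n_views) if views is None else views
    for v in view_ids:
        ang = geom.angles_deg[v]
        M, _Mt, Mg = _rotation_ops(n, geom.pitch_mm[0], ang)
        xr = (M @ vol2).reshape(n, n, nz)
        if mu2 is not None:
            mur = (Mg @ mu2).reshape(n, n, nz)
            xr = xr * _attenuation_weights(mur, sy)
        if sigmas is None:
            out[v] = xr.sum(axis=1)
        else:
            acc = np.zeros((n, nz))
            for j in range(n):
                sig = sigmas[j]
                if sig > 1e-6:
                    acc += ndimage.gaussian_filter(
                        xr[:, j, :],
                        (sig / geom.pitch_mm[0], sig / geom.pitch_mm[1]),
                        mode="constant",
                    )
                else:
                    acc += xr[:, j, :]
            out[v] = acc
    return ProjectionSet(geom, out * efficiency, "mean_primary")


def backproject(
    p: ProjectionSet,
    mu: VoxelVolume | None,
    grid,
    geom: ProjectionGeometry | None = None,
    cdr: CDRModel | None = None,
    efficiency: float = 1.0,
    views: np.ndarray | None = None,
) -> VoxelVolume:
    """Exact adjoint of :func:`project` (optionally over a view subset)."""
    geom = geom or p.geometry
    cdr = cdr or CDRModel.off()
    ref = VoxelVolume(grid, np.zeros(grid.shape), "activity_MBq")
    _check_compat(ref, geom)
    if mu is not None and mu.grid != grid:
        raise ValueError("attenuation grid mismatch")
    n, _ny, nz = grid.shape
    sy = grid.voxel_size_mm[1]
    sigmas = _plane_sigmas(geom, n, sy, cdr) if cdr.enabled else None
    mu2 = mu.values.reshape(n * n, nz) if mu is not None else None
    acc2 = np.zeros((n * n, nz))
    view_ids = range(geom.n_views) if views is None else views
    for v in view_ids:
        ang = geom.angles_deg[v]
        M, Mt, Mg = _rotation_ops(n, geom.pitch_mm[0], ang)
        g = p.values[v] * efficiency
        if sigmas is None:
            t = np.broadcast_to(g[:, None, :], (n, n, nz)).copy()
        else:
            t = np.empty((n, n, nz))
            for j in range(n):
                sig = sigmas[j]
                if sig > 1e-6:
                    t[:, j, :] = ndimage.gaussian_filter(
                        g, (sig / geom.pitch_mm[0], sig / geom.pitch_mm[1]), mode="constant"
                    )
                else:
                    t[:, j, :] = g
        if mu2 is not None:
            mur = (Mg @ mu2).reshape(n, n, nz)
            t = t * _attenuation_weights(mur, sy)
        acc2 += Mt @ t.reshape(n * n, nz)
    return VoxelVolume(grid, acc2.reshape(n, n, nz), "activity_MBq")


def project_attenuation(mu: VoxelVolume, geom: ProjectionGeometry) -> ProjectionSet:
    """Straight-line integrals of mu per view (dimensionless), no CDR/efficiency."""
    if mu.values.min() < 0:
        raise ValueError("attenuation must be >= 0")
    _check_compat(mu, geom)
    n, _ny, nz = mu.grid.shape
    dy_cm = mu.grid.voxel_size_mm[1] / 10.0
    mu2 = mu.values.reshape(n * n, nz)
    out = np.zeros((geom.n_views, n, nz))
    for v, ang in enumerate(geom.angles_deg):
        _M, _Mt, Mg = _rotation_ops(n, geom.pitch_mm[0], ang)
        mur = (Mg @ mu2).reshape(n, n, nz)
        out[v] = mur.sum(axis=1) * dy_cm
    return ProjectionSet(geom, out, "attenuation_line_integral")


def add_poisson_noise(
    p: ProjectionSet, target_total_counts: float, seed: int
) -> tuple[ProjectionSet, float]:
    """Scale mean projections to a clinical count level and draw Poisson counts.

    Returns (noisy counts, scale) where scale = target / sum(mean); the scale
    is needed downstream to keep scatter estimates in the same count units.
    """
    if p.kind not in ("mean_primary", "mean_scatter"):
        raise ValueError("Poisson noise applies to mean-valued projections")
    total = p.total()
    if target_total_counts == 0 and total == 0:
        return ProjectionSet(p.geometry, np.zeros_like(p.values), "noisy_counts"), 1.0
    if target_total_counts < 0:
        raise ValueError("target counts must be >= 0")
    if total <= 0:
        raise ValueError("cannot scale an all-zero mean projection to positive counts")
    scale = target_total_counts / total
    rng = np.random.default_rng(seed)
    counts = rng.poisson(scale * p.values).astype(np.float64)
    return ProjectionSet(p.geometry, counts, "noisy_counts"), scale


# ---------------------------------------------------------------------------
# HDF5 container


def save_projections(p: ProjectionSet, path: str, extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=p.values)
        f.attrs["kind"] = p.kind
        g = p.geometry
        f.attrs.update(
            n_views=g.n_views, n_bins_u=g.n_bins_u, n_bins_v=g.n_bins_v,
            pitch_mm=g.pitch_mm, radius_mm=g.radius_mm,
            energy_window_keV=g.energy_window_keV,
        )
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def load_projections(path: str) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        geom = ProjectionGeometry(
            n_views=int(f.attrs["n_views"]),
            n_bins_u=int(f.attrs["n_bins_u"]),
            n_bins_v=int(f.attrs["n_bins_v"]),
            pitch_mm=tuple(f.attrs["pitch_mm"]),
            radius_mm=float(f.attrs["radius_mm"]),
            energy_window_keV=tuple(f.attrs["energy_window_keV"]),
        )
        return ProjectionSet(geom, f["values"][()], str(f.attrs["kind"]))
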
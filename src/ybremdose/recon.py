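"""Ordered-subsets EM reconstruction with attenuation, scatter mean and CDR.

Implements the classic multiplicative OS-EM update for the Poisson model
y ~ Poisson(Ax + r), cycling over view subsets:

    x <- x * A_s^T( y_s / (A_s x + r_s) ) / A_s^T 1

With one subset this is exactly MLEM, whose Poisson log-likelihood is
non-decreasing per iteration.  No post-filtering is applied; the default
schedule is 4 subsets x 16 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projector import CDRModel, ProjectionGeometry, ProjectionSet, backproject, project
from .volumes import VoxelGrid, VoxelVolume

_DENOM_FLOOR = 1e-12  # guards 0/0 in the multiplicative update


@dataclass(frozen=True)
class OsemConfig:
    n_subsets: int = 4
    n_iterations: int = 16
    subset_order: str = "bit_reversal"  # or "sequential"
    track_likelihood: bool = False

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ValueError("subsets and iterations must be >= 1")


@dataclass
class SystemModel:
    mu: VoxelVolume | None
    geom: ProjectionGeometry
    cdr: CDRModel
    efficiency: float = 1.0


def _bit_reversal_order(n: int) -> list[int]:
    if n == 1:
        return [0]
    bits = max(1, (n - 1).bit_length())
    order = sorted(range(n), key=lambda i: int(format(i, f"0{bits}b")[::-1], 2))
    return order


def _subsets(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Interleaved subsets: subset s takes views s, s+n_subsets, ... so each
    subset spans the full angular range with maximal spacing."""
    return [np.arange(s, n_views, n_subsets) for s in range(n_subsets)]


def poisson_loglik(y: ProjectionSet, mean: np.ndarray) -> float:
    """sum_i y_i log(mean_i) - mean_i, with the 0*log0 convention."""
    m = np.maximum(mean, _DENOM_FLOOR)
    return float(np.sum(y.values * np.log(m) - m))


def osem(
    y: ProjectionSet,
    system: SystemModel,
    scatter_mean: ProjectionSet | None,
    cfg: OsemConfig = OsemConfig(),
    grid: VoxelGrid | None = None,
) -> tuple[VoxelVolume, dict]:
    """OS-EM reconstruction of per-voxel activity from noisy counts.

    Returns (activity volume, info) where info records the subset schedule
    and, when ``cfg.track_likelihood``, the Poisson log-likelihood after each
    full iteration.
    """
    geom = y.geometry
    if geom.n_views % cfg.n_subsets != 0:
        raise ValueError(
            f"subset count {cfg.n_subsets} does not divide {geom.n_views} views"
        )
    if scatter_mean is not None:
        if scatter_mean.geometry != geom:
            raise ValueError("scatter mean and measurements must share geometry")
        rbar = scatter_mean.values
    else:
        rbar = np.zeros_like(y.values)
    if grid is None:
        if system.mu is None:
            raise ValueError("a reconstruction grid is required when mu is absent")
        grid = system.mu.grid

    subsets = _subsets(geom.n_views, cfg.n_subsets)
    order = (
        _bit_reversal_order(cfg.n_subsets)
        if cfg.subset_order == "bit_reversal"
        else list(range(cfg.n_subsets))
    )

    sens = []
    ones = ProjectionSet(geom, np.ones_like(y.values), "mean_primary")
    for s in subsets:
        b = backproject(ones, system.mu, grid, geom, system.cdr, system.efficiency, views=s)
        sens.append(b.values)

    # uniform start inside the attenuation support (all-ones when mu is absent)
    if system.mu is not None and system.mu.values.max() > 0:
        support = system.mu.values > 0
        if not support.any():
            support = np.ones(grid.shape, dtype=bool)
    else:
        support = np.ones(grid.shape, dtype=bool)
    x = np.where(support, 1.0, 0.0)

    info: dict = {"schedule": [], "loglik": []}
    for it in range(cfg.n_iterations):
        for s_idx in order:
            views = subsets[s_idx]
            xv = VoxelVolume(grid, x, "activity_MBq")
            ax = project(xv, system.mu, geom, system.cdr, system.efficiency, views=views)
            denom = np.maximum(ax.values + rbar, _DENOM_FLOOR)
            ratio = np.zeros_like(y.values)
            ratio[views] = y.values[views] / denom[views]
            corr = backproject(
                ProjectionSet(geom, ratio, "mean_primary"),
                system.mu, grid, geom, system.cdr, system.efficiency, views=views,
            ).values
            good = sens[s_idx] > 0
            x = np.where(good, x * corr / np.where(good, sens[s_idx], 1.0), 0.0)
            info["schedule"].append((it, int(s_idx)))
        if cfg.track_likelihood:
            xv = VoxelVolume(grid, x, "activity_MBq")
            ax_all = project(xv, system.mu, geom, system.cdr, system.efficiency)
            info["loglik"].append(poisson_loglik(y, ax_all.values + rbar))
    return VoxelVolume(grid, x, "activity_MBq"), info


def mlem(y: ProjectionSet, system: SystemModel, scatter_mean, n_iterations: int,
         grid: VoxelGrid | None = None, track_likelihood: bool = False):
    """MLEM = OS-EM with a single subset."""
    cfg = OsemConfig(n_subsets=1, n_iterations=n_iterations,
                     track_likelihood=track_likelihood)
    return osem(y, system, scatter_mean, cfg, grid)


def resample_to_ct(x: VoxelVolume, ct_grid: VoxelGrid) -> VoxelVolume:
    """Trilinear resampling of a reconstruction onto the CT grid.

    Interpolates activity *concentration* in the shared world frame, then
    rescales globally so total activity is preserved exactly over the
    overlapping field of view.
    """
    src = x.grid
    # overlap check in world coordinates
    for a in range(3):
        lo_s = src.origin_mm[a]
        hi_s = lo_s + src.extent_mm()[a]
        lo_t = ct_grid.origin_mm[a]
        hi_t = lo_t + ct_grid.extent_mm()[a]
        if hi_t <= lo_s or hi_s <= lo_t:
            raise ValueError("reconstruction and CT grids do not overlap")
    if ct_grid == src:
        return x.copy()
    conc = x.values / src.voxel_volume_mm3
    coords = np.meshgrid(
        *[(ct_grid.centers_mm(a) - src.origin_mm[a]) / src.voxel_size_mm[a] - 0.5 for a in range(3)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(conc, np.stack(coords), order=1, mode="nearest")
    out = np.maximum(out, 0.0) * ct_grid.voxel_volume_mm3
    s_in, s_out = x.values.sum(), out.sum()
    if s_out > 0 and s_in > 0:
        out *= s_in / s_out
    return VoxelVolume(ct_grid, out, x.quantity)


def resample_values(x: VoxelVolume, grid: VoxelGrid) -> VoxelVolume:
    """Trilinear *value* interpolation onto another grid in the shared world
    frame (for intensive quantities such as attenuation or density)."""
    if grid == x.grid:
        return x.copy()
    src = x.grid
    coords = np.meshgrid(
        *[(grid.centers_mm(a) - src.origin_mm[a]) / src.voxel_size_mm[a] - 0.5 for a in range(3)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(x.values, np.stack(coords), order=1, mode="nearest")
    return VoxelVolume(grid, out, x.quantity)
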
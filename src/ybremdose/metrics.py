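"""Quantitative evaluation: NMAE, NRMSE, dose-rate volume histograms and
lesion-to-background ratios.

A note on NMAE: as printed and reported in this field's dosimetry tables it
is the absolute *difference of VOI means* over the GT mean -- a bias-of-means
metric, despite the name.  `nmae` implements exactly that.  A conventional
voxel-wise mean-absolute-error variant is provided separately as
`voxelwise_mae` and is never used interchangeably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import VoxelVolume


def _values(x) -> np.ndarray:
    if isinstance(x, VoxelVolume):
        return x.values
    if hasattr(x, "volume"):  # DoseRateMap
        return x.volume.values
    return np.asarray(x, dtype=np.float64)


def nmae(gt, est, mask) -> float:
    """Normalized mean absolute error, percent: |mean(x) - mean(xhat)| / mean(x).

    This is the bias of VOI means (the printed definition), not a voxel-wise
    absolute error; see `voxelwise_mae` for the latter.
    """
    x, xh = _values(gt), _values(est)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI mask")
    mx = x[m].mean()
    if mx <= 0:
        raise ValueError("NMAE undefined: GT mean over the VOI is not positive")
    return float(abs(mx - xh[m].mean()) / mx * 100.0)


def voxelwise_mae(gt, est, mask) -> float:
    """Voxel-wise mean absolute error over the GT mean, percent (alternative
    metric, clearly distinct from the printed NMAE definition)."""
    x, xh = _values(gt), _values(est)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI mask")
    mx = x[m].mean()
    if mx <= 0:
        raise ValueError("undefined: GT mean over the VOI is not positive")
    return float(np.abs(x[m] - xh[m]).mean() / mx * 100.0)


def nrmse(gt, est, mask) -> float:
    """Normalized RMSE, percent: RMSE over the root-mean-square of the GT."""
    x, xh = _values(gt), _values(est)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI mask")
    rms = np.sqrt((x[m] ** 2).mean())
    if rms <= 0:
        raise ValueError("NRMSE undefined: GT is identically zero on the VOI")
    return float(np.sqrt(((x[m] - xh[m]) ** 2).mean()) / rms * 100.0)


# ---------------------------------------------------------------------------
# cumulative dose-rate volume histogram


@dataclass
class DRVH:
    """Cumulative DRVH: fraction of VOI volume receiving >= each threshold."""

    thresholds: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must ascend")
        if np.any(np.diff(self.fractions) > 1e-12):
            raise ValueError("coverage fractions must be non-increasing")

    def d_at(self, volume_fraction: float) -> float:
        """D(f): the largest threshold d with coverage fraction(>= d) >= f,
        i.e. the minimum dose rate received by the hottest f of the volume."""
        ok = self.fractions >= volume_fraction
        if not ok.any():
            return float(self.thresholds[0])
        return float(self.thresholds[np.nonzero(ok)[0][-1]])

    @property
    def d10(self) -> float:
        return self.d_at(0.10)

    @property
    def d90(self) -> float:
        return self.d_at(0.90)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fraction_ge": self.fractions})


def drvh(dose_map, mask, n_bins: int | None = None) -> DRVH:
    """Cumulative histogram over the VOI.

    Thresholds are the sorted voxel values (0 prepended), so the curve starts
    at fraction 1 and ends at 0 above the maximum.
    """
    v = _values(dose_map)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI mask")
    vals = np.sort(v[m])
    n = vals.size
    if n_bins is not None and n > n_bins:
        qs = np.linspace(0, 1, n_bins)
        thr = np.quantile(vals, qs)
    else:
        thr = vals
    thr = np.unique(np.concatenate([[0.0], thr, [vals[-1] * (1 + 1e-12) + 1e-300]]))
    frac = (n - np.searchsorted(vals, thr, side="left")) / n
    return DRVH(thr, frac)


# ---------------------------------------------------------------------------
# lesion-to-background ratio


def _shift_mask(idx: np.ndarray, offset: np.ndarray, shape) -> np.ndarray | None:
    s = idx + offset
    if s.min() < 0 or np.any(s >= np.asarray(shape)):
        return None
    return s


def lesion_to_background(
    dose_map,
    lesion_mask: np.ndarray,
    liver_mask: np.ndarray,
    all_lesion_masks: list[np.ndarray],
    seed: int = 0,
    search_radius_mm: float = 50.0,
    voxel_size_mm=(1.0, 1.0, 1.0),
    max_candidates: int = 2000,
) -> tuple[float, np.ndarray]:
    """Mean-dose ratio between a lesion and a shape-matched background VOI.

    The background VOI is the lesion mask translated by an integer voxel
    offset (searched nearest-first within the radius) so that it lies fully
    inside the liver and is disjoint from every lesion; among feasible
    placements the one minimizing the local coefficient of variation of the
    map is chosen, mimicking a "nearby uniform region" selection (evaluation
    is bounded to the ``max_candidates`` nearest feasible placements).  The
    background has exactly the lesion's voxel count and shape.
    """
    v = _values(dose_map)
    les = np.asarray(lesion_mask, dtype=bool)
    liver = np.asarray(liver_mask, dtype=bool)
    if not les.any():
        raise ValueError("empty lesion mask")
    forbidden = ~liver
    for m in all_lesion_masks:
        forbidden |= np.asarray(m, dtype=bool)
    idx = np.argwhere(les)
    sizes = np.asarray(voxel_size_mm, dtype=float)
    rad_vox = np.maximum(1, np.floor(search_radius_mm / sizes).astype(int))
    offs = np.stack(np.meshgrid(*[np.arange(-r, r + 1) for r in rad_vox], indexing="ij"),
                    axis=-1).reshape(-1, 3)
    d_mm = np.linalg.norm(offs * sizes, axis=1)
    keep = (d_mm > 0) & (d_mm <= search_radius_mm)
    offs, d_mm = offs[keep], d_mm[keep]
    order = np.argsort(d_mm, kind="stable")
    # FFT overlap counts make the per-offset feasibility test O(1)
    from scipy.signal import fftconvolve

    overlap = fftconvolve(forbidden.astype(np.float64),
                          les[::-1, ::-1, ::-1].astype(np.float64), mode="full")
    base = np.asarray(les.shape) - 1
    imin, imax = idx.min(axis=0), idx.max(axis=0)
    best = None  # (cov, distance, shifted_idx)
    n_eval = 0
    for oi in order:
        off = offs[oi]
        if np.any(imin + off < 0) or np.any(imax + off >= np.asarray(v.shape)):
            continue
        if overlap[tuple(base + off)] > 0.5:
            continue
        s = idx + off
        vals = v[s[:, 0], s[:, 1], s[:, 2]]
        mu = vals.mean()
        cov = vals.std() / mu if mu > 0 else np.inf
        if best is None or cov < best[0] - 1e-12:
            best = (cov, d_mm[oi], s)
        n_eval += 1
        if n_eval >= max_candidates:
            break
    if best is None:
        raise ValueError(
            f"no feasible background placement within {search_radius_mm} mm: "
            f"lesion has {idx.shape[0]} voxels, liver {int(liver.sum())}"
        )
    s = best[2]
    bg = np.zeros_like(les)
    bg[s[:, 0], s[:, 1], s[:, 2]] = True
    ratio = float(v[les].mean() / v[bg].mean())
    return ratio, bg


# ---------------------------------------------------------------------------
# reports


@dataclass
class MetricsReport:
    records: list[dict] = field(default_factory=list)

    def add_voi(self, name: str, gt, est, mask) -> dict:
        m = np.asarray(mask, dtype=bool)
        rec = {
            "voi": name,
            "n_p": int(m.sum()),
            "nmae_pct": nmae(gt, est, m),
            "nrmse_pct": nrmse(gt, est, m),
            "mean_gt": float(_values(gt)[m].mean()),
            "mean_est": float(_values(est)[m].mean()),
        }
        self.records.append(rec)
        return rec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def aggregate(self) -> dict:
        df = self.to_frame()
        return {
            "nmae_mean": float(df["nmae_pct"].mean()),
            "nmae_sd": float(df["nmae_pct"].std(ddof=1)) if len(df) > 1 else 0.0,
            "nrmse_mean": float(df["nrmse_pct"].mean()),
            "nrmse_sd": float(df["nrmse_pct"].std(ddof=1)) if len(df) > 1 else 0.0,
        }

    def save(self, csv_path: str, json_path: str | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path:
            with open(json_path, "w") as f:
                json.dump({"records": self.records, "aggregate": self.aggregate()}, f, indent=1)
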
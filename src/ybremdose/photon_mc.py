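"""Simplified photon Monte Carlo for 90Y bremsstrahlung SPECT projections.

Produces ground-truth scatter and primary mean projections from an
activity/density phantom, for training and evaluating the scatter network.
Physics: photons are emitted isotropically from decay sites sampled from the
activity map, with energies drawn from a thick-target bremsstrahlung spectrum
I(E) ~ (Emax - E)/E on [50, 2280] keV.  Transport uses Woodcock (delta)
tracking through the density map with water cross sections scaled by local
density: incoherent (Compton) scattering with exact Klein-Nishina
energy/angle sampling plus photoelectric absorption; coherent scattering is
neglected (small above the 105 keV window edge).  A photon escaping the
volume toward a detector within the collimator acceptance cone is scored
into the geometrically mapped bin if its Gaussian-blurred energy falls in
the acquisition window; photons with >= 1 interaction score to scatter,
0 interactions to primary.  Scoring is analog (binary), with no forced
detection, so the estimator is simple and auditable.

Means are normalised to counts per decay then scaled by total activity, so
both outputs are linear in activity.  An optional Gaussian smoothing of the
scatter mean provides a denoised training label at desk-scale history counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .projector import ProjectionGeometry, ProjectionSet
from .volumes import VoxelVolume

E_MAX_KEV = 2280.0
MEC2_KEV = 510.998950
_RE_CM = 2.8179403262e-13  # classical electron radius
_ELECTRONS_PER_G_WATER = 3.3428e23


# ---------------------------------------------------------------------------
# emission spectrum


@dataclass
class BremsSpectrum:
    """Tabulated photon emission spectrum with inverse-CDF sampling."""

    energies_keV: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.energies_keV = np.asarray(self.energies_keV, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.energies_keV.ndim != 1 or self.energies_keV.size == 0:
            raise ValueError("spectrum table must be a non-empty 1-D array")
        if self.intensities.shape != self.energies_keV.shape:
            raise ValueError("energies and intensities must have the same length")
        if np.any(self.intensities < 0) or self.intensities.sum() <= 0:
            raise ValueError("intensities must be >= 0 with positive sum")
        if self.energies_keV.max() > E_MAX_KEV:
            raise ValueError(f"spectrum support must not exceed {E_MAX_KEV} keV")
        self.intensities = self.intensities / self.intensities.sum()
        self._cdf = np.cumsum(self.intensities)

    @classmethod
    def thick_target(cls, e_min_keV: float = 50.0, step_keV: float = 1.0) -> "BremsSpectrum":
        """Analytic thick-target shape I(E) ~ (Emax - E)/E, tabulated at 1 keV."""
        e = np.arange(e_min_keV, E_MAX_KEV + 0.5 * step_keV, step_keV)
        return cls(e, (E_MAX_KEV - e) / e)

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return self.energies_keV[np.searchsorted(self._cdf, rng.random(n), side="right").clip(0, self.energies_keV.size - 1)]


def sample_spectrum(spec: BremsSpectrum, n: int, seed: int) -> np.ndarray:
    """i.i.d. draws from the tabulated spectrum (inverse-CDF on the table)."""
    return spec.sample(n, seed)


# ---------------------------------------------------------------------------
# cross sections (water, scaled by density)


def klein_nishina_total_cm2(energy_keV: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    a = np.asarray(energy_keV, dtype=np.float64) / MEC2_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * _RE_CM**2 * (t1 + t2 - t3)


def compton_mu_rho(energy_keV: np.ndarray) -> np.ndarray:
    """Incoherent mass attenuation coefficient of water, cm^2/g."""
    return klein_nishina_total_cm2(energy_keV) * _ELECTRONS_PER_G_WATER


# Coarse photoelectric mass attenuation of water (cm^2/g), log-log interpolated.
_PE_E_KEV = np.array([40, 50, 60, 80, 100, 150, 200, 300, 500, 1000, 2280], dtype=float)
_PE_MU_RHO = np.array([6.5e-3, 3.2e-3, 1.8e-3, 7.0e-4, 3.4e-4, 9.0e-5,
                       3.5e-5, 9.5e-6, 1.9e-6, 2.6e-7, 3.0e-8])


def photoelectric_mu_rho(energy_keV: np.ndarray) -> np.ndarray:
    e = np.clip(np.asarray(energy_keV, dtype=np.float64), _PE_E_KEV[0], _PE_E_KEV[-1])
    return np.exp(np.interp(np.log(e), np.log(_PE_E_KEV), np.log(_PE_MU_RHO)))


def sample_klein_nishina_cos(energy_keV: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Scattering-angle cosines from the Klein-Nishina differential cross
    section by rejection against its forward maximum (f(cos=1) = 2)."""
    a = np.asarray(energy_keV, dtype=np.float64) / MEC2_KEV
    n = a.size
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        mu = rng.uniform(-1.0, 1.0, todo.size)
        k = 1.0 / (1.0 + a[todo] * (1.0 - mu))
        f = k + k**3 - (k**2) * (1.0 - mu**2)
        acc = rng.random(todo.size) * 2.0 < f
        out[todo[acc]] = mu[acc]
        todo = todo[~acc]
    return out


def _rotate_directions(d: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors d by polar angle theta about themselves (azimuth phi)."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    # build an orthonormal frame around d
    ref = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    out = (
        d * cos_t[:, None]
        + e1 * (sin_t * np.cos(phi))[:, None]
        + e2 * (sin_t * np.sin(phi))[:, None]
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class McConfig:
    n_histories: int = 200_000
    seed: int = 0
    energy_resolution_at_140: float = 0.095  # FWHM fraction, scales as 1/sqrt(E)
    acceptance_half_angle_deg: float = 2.0
    low_energy_cutoff_keV: float = 50.0
    label_smoothing_fwhm_bins: float = 1.0
    spectrum: BremsSpectrum = field(default_factory=BremsSpectrum.thick_target)
    max_interactions: int = 200

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")

    def config_hash(self) -> str:
        payload = {
            "n_histories": self.n_histories, "seed": self.seed,
            "eres": self.energy_resolution_at_140,
            "half_angle": self.acceptance_half_angle_deg,
            "cutoff": self.low_energy_cutoff_keV,
            "smooth": self.label_smoothing_fwhm_bins,
            "spectrum_sha": hashlib.sha256(self.spectrum.energies_keV.tobytes()
                                           + self.spectrum.intensities.tobytes()).hexdigest()[:12],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def energy_fwhm_keV(energy_keV: np.ndarray, fraction_at_140: float) -> np.ndarray:
    """Gaussian detector resolution: FWHM fraction f(E) = f140 * sqrt(140/E)."""
    return fraction_at_140 * np.sqrt(140.0 * np.asarray(energy_keV, dtype=np.float64))


# ---------------------------------------------------------------------------
# transport + scoring


def simulate_projections(
    activity: VoxelVolume,
    density: VoxelVolume,
    geom: ProjectionGeometry,
    cfg: McConfig,
) -> tuple[ProjectionSet, ProjectionSet]:
    """Analog MC estimate of (mean scatter, mean primary) projections."""
    if activity.grid != density.grid:
        raise ValueError("activity and density must share one grid")
    act = activity.values
    total_act = act.sum()
    if total_act <= 0:
        raise ValueError("activity map is empty")
    grid = activity.grid
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_histories

    # decay sites ~ activity, uniform jitter inside the voxel
    pflat = (act / total_act).ravel()
    vox = rng.choice(act.size, size=n, p=pflat)
    ijk = np.column_stack(np.unravel_index(vox, act.shape)).astype(np.float64)
    sizes = np.asarray(grid.voxel_size_mm)
    half_extent = 0.5 * np.asarray(grid.extent_mm())
    pos = (ijk + rng.random((n, 3))) * sizes - half_extent  # mm, grid-centred

    energy = cfg.spectrum.sample(n, rng)
    cost = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sint = np.sqrt(1.0 - cost**2)
    dirs = np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])

    rho = density.values
    rho_max = float(rho.max())
    nscat = np.zeros(n, dtype=np.int32)
    alive = np.ones(n, dtype=bool)
    escaped = np.zeros(n, dtype=bool)

    def inside(p: np.ndarray) -> np.ndarray:
        return np.all((p >= -half_extent) & (p < half_extent), axis=1)

    if rho_max <= 0:
        escaped[:] = True
        alive[:] = False

    it = 0
    while alive.any() and it < cfg.max_interactions:
        it += 1
        idx = np.flatnonzero(alive)
        e = energy[idx]
        mu_rho_tot = compton_mu_rho(e) + photoelectric_mu_rho(e)
        mu_max = rho_max * mu_rho_tot  # cm^-1
        step_mm = -np.log(rng.random(idx.size)) / mu_max * 10.0
        pos[idx] += dirs[idx] * step_mm[:, None]
        out = ~inside(pos[idx])
        escaped[idx[out]] = True
        alive[idx[out]] = False
        idx = idx[~out]
        if idx.size == 0:
            continue
        vi = np.floor((pos[idx] + half_extent) / sizes).astype(np.int64)
        vi = np.clip(vi, 0, np.asarray(act.shape) - 1)
        rho_loc = rho[vi[:, 0], vi[:, 1], vi[:, 2]]
        real = rng.random(idx.size) < rho_loc / rho_max
        idx = idx[real]
        if idx.size == 0:
            continue
        e = energy[idx]
        p_pe = photoelectric_mu_rho(e) / (compton_mu_rho(e) + photoelectric_mu_rho(e))
        absorbed = rng.random(idx.size) < p_pe
        alive[idx[absorbed]] = False
        idx = idx[~absorbed]
        if idx.size == 0:
            continue
        mu_s = sample_klein_nishina_cos(energy[idx], rng)
        energy[idx] = energy[idx] / (1.0 + (energy[idx] / MEC2_KEV) * (1.0 - mu_s))
        dirs[idx] = _rotate_directions(dirs[idx], mu_s, rng.uniform(0, 2 * np.pi, idx.size))
        nscat[idx] += 1
        low = energy[idx] < cfg.low_energy_cutoff_keV
        alive[idx[low]] = False

    # detector scoring
    e_esc = energy[escaped]
    blurred = e_esc + rng.standard_normal(e_esc.size) * (
        energy_fwhm_keV(e_esc, cfg.energy_resolution_at_140) / 2.3548200450309493
    )
    lo, hi = geom.energy_window_keV
    in_win = (blurred >= lo) & (blurred <= hi)
    sel = np.flatnonzero(escaped)[in_win]

    d = dirs[sel]
    p = pos[sel]
    is_scatter = nscat[sel] >= 1
    cos_acc = np.cos(np.deg2rad(cfg.acceptance_half_angle_deg))
    shape = (geom.n_views, geom.n_bins_u, geom.n_bins_v)
    scatter = np.zeros(shape)
    primary = np.zeros(shape)
    th = np.deg2rad(geom.angles_deg)
    for v in range(geom.n_views):
        nv = np.array([-np.sin(th[v]), np.cos(th[v]), 0.0])
        uv = np.array([np.cos(th[v]), np.sin(th[v]), 0.0])
        acc = d @ nv >= cos_acc
        if not acc.any():
            continue
        u = p[acc] @ uv
        w = p[acc, 2]
        bu = np.floor(u / geom.pitch_mm[0] + geom.n_bins_u / 2.0).astype(np.int64)
        bv = np.floor(w / geom.pitch_mm[1] + geom.n_bins_v / 2.0).astype(np.int64)
        ok = (bu >= 0) & (bu < geom.n_bins_u) & (bv >= 0) & (bv < geom.n_bins_v)
        sc = is_scatter[acc]
        np.add.at(scatter[v], (bu[ok & sc], bv[ok & sc]), 1.0)
        np.add.at(primary[v], (bu[ok & ~sc], bv[ok & ~sc]), 1.0)

    norm = total_act / n  # counts per decay -> scaled to activity
    scatter *= norm
    primary *= norm
    if cfg.label_smoothing_fwhm_bins > 0:
        sig = cfg.label_smoothing_fwhm_bins / 2.3548200450309493
        scatter = ndimage.gaussian_filter(scatter, (0, sig, sig), mode="constant")
    return (
        ProjectionSet(geom, scatter, "mean_scatter"),
        ProjectionSet(geom, primary, "mean_primary"),
    )
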
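"""End-to-end orchestration: desk protocol, experiment arms and fixtures.

The pipeline mirrors the three-stage framework: (I) CNN scatter estimation in
projection space, (II) OS-EM reconstruction with attenuation, CDR and the
scatter-mean correction, (III) voxel dose-rate maps by DVK convolution,
direct MC, or the residual dose network.  The four arms are

    CNN_SC+DblurDoseNet   the full framework
    CNN_SC+DVK            fast kernel dosimetry on the corrected recon
    CNN_SC+MC             direct MC dosimetry on the corrected recon
    noSC+single_stage     ablation: one network from the uncorrected recon

Desk protocol
-------------
Phantoms live on the 128x128x64 grid at 2 mm; SPECT acquisition uses 64
views of 64x32 bins at 4.8 mm (the paper-scale 128-view 128x80 geometry
remains available through ProjectionGeometry defaults) and the recon grid is
64x64x32 at 4.8 mm, centred on the phantom frame.  Measured projections are
composed as y ~ Poisson(Ax + r) at ~1e7 total counts, where r is the photon-
MC scatter mean rescaled so that the scatter-to-primary ratio matches the
MC simulation.  The attenuation map uses the water mass-attenuation
coefficient at 150 keV, mid-acquisition-window.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .beta_dose import (DoseKernel, DoseRateMap, dvk_convolve, generate_dvk,
                        load_kernel, mc_dose_rate, save_kernel)
from .dose_net import (DoseNet, DoseStudy, load_dose_checkpoint, predict_dose,
                       single_stage_variant)
from .phantoms import (DESK_GRID, PhantomConfig, density_to_attenuation,
                       make_virtual_patient)
from .photon_mc import McConfig, simulate_projections
from .projector import (CDRModel, ProjectionGeometry, ProjectionSet,
                        add_poisson_noise, project, project_attenuation,
                        save_projections)
from .recon import OsemConfig, SystemModel, osem, resample_to_ct, resample_values
from .scatter_net import (ScatterNet, load_scatter_checkpoint, predict_scatter)
from .volumes import VoxelGrid, VoxelVolume, VOISet, save_volume

ARMS = ("CNN_SC+DblurDoseNet", "CNN_SC+DVK", "CNN_SC+MC", "noSC+single_stage")

ATTEN_ENERGY_KEV = 150.0  # mid-window effective photon energy for the mu map
DESK_TARGET_COUNTS = 1e7


def desk_geometry() -> ProjectionGeometry:
    return ProjectionGeometry(n_views=64, n_bins_u=64, n_bins_v=32,
                              pitch_mm=(4.8, 4.8), radius_mm=250.0)


def desk_cdr() -> CDRModel:
    return CDRModel(c0_mm=2.0, c1=0.05)


def recon_grid_for(phantom_grid: VoxelGrid, geom: ProjectionGeometry) -> VoxelGrid:
    """Reconstruction grid matching the detector sampling, centred on the
    phantom's world frame."""
    shape = (geom.n_bins_u, geom.n_bins_u, geom.n_bins_v)
    sizes = (geom.pitch_mm[0], geom.pitch_mm[0], geom.pitch_mm[1])
    center = [phantom_grid.origin_mm[a] + 0.5 * phantom_grid.extent_mm()[a] for a in range(3)]
    origin = tuple(center[a] - 0.5 * shape[a] * sizes[a] for a in range(3))
    return VoxelGrid(shape, sizes, origin)


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# measurement simulation (study conditions for training and evaluation)


@dataclass
class Measurement:
    """Everything the downstream stages need for one simulated acquisition."""

    geom: ProjectionGeometry
    y: ProjectionSet                 # noisy counts
    scatter_true: ProjectionSet      # scatter mean, count units (GT for SC)
    atten_proj: ProjectionSet        # projected attenuation map
    mu_recon: VoxelVolume            # attenuation on the recon grid
    x_true_recon: VoxelVolume        # true activity resampled to recon grid
    count_scale: float


def _fine_primary(activity, mu, geom, cdr):
    """Primary mean projections computed at half the detector pitch.

    The data-generating forward model is sampled twice as finely as the
    reconstruction model and the resulting projections are 2x2-binned, so
    the reconstruction never inverts the exact operator that generated its
    data (inverse-crime avoidance; the reference pipeline has the same
    asymmetry between its MC data generator and its reconstruction model).
    """
    fine_geom = ProjectionGeometry(
        n_views=geom.n_views, n_bins_u=2 * geom.n_bins_u,
        n_bins_v=2 * geom.n_bins_v,
        pitch_mm=(geom.pitch_mm[0] / 2, geom.pitch_mm[1] / 2),
        radius_mm=geom.radius_mm, energy_window_keV=geom.energy_window_keV)
    fgrid = recon_grid_for(activity.grid, fine_geom)
    x_f = resample_to_ct(activity, fgrid)
    mu_f = resample_values(mu, fgrid)
    p = project(x_f, mu_f, fine_geom, cdr, efficiency=1.0)
    v = p.values.reshape(geom.n_views, geom.n_bins_u, 2, geom.n_bins_v, 2).sum(axis=(2, 4))
    return ProjectionSet(geom, v, "mean_primary")


def simulate_measurement(
    activity: VoxelVolume,
    density: VoxelVolume,
    geom: ProjectionGeometry | None = None,
    cdr: CDRModel | None = None,
    mc_histories: int = 200_000,
    target_counts: float = DESK_TARGET_COUNTS,
    seed: int = 0,
    fine_forward: bool = True,
) -> Measurement:
    """Compose y ~ Poisson(Ax + r) with an MC-derived scatter mean r.

    The photon MC provides the scatter-to-primary ratio and the scatter
    shape; a finely sampled deterministic forward model provides the
    primary (see :func:`_fine_primary`), so the reconstruction model is a
    deliberately coarser approximation of the data generator.
    """
    geom = geom or desk_geometry()
    cdr = cdr or desk_cdr()
    rgrid = recon_grid_for(activity.grid, geom)
    mu = density_to_attenuation(density, ATTEN_ENERGY_KEV)
    mu_r = resample_values(mu, rgrid)
    x_r = resample_to_ct(activity, rgrid)
    if fine_forward:
        primary = _fine_primary(activity, mu, geom, cdr)
    else:
        primary = project(x_r, mu_r, geom, cdr, efficiency=1.0)
    sc_mc, pr_mc = simulate_projections(
        activity, density, geom, McConfig(n_histories=mc_histories, seed=seed)
    )
    if pr_mc.total() <= 0 or sc_mc.total() <= 0:
        raise RuntimeError("photon MC produced no detected counts; raise n_histories")
    scatter_mean = sc_mc.values * (primary.total() / pr_mc.total())
    total_mean = ProjectionSet(geom, primary.values + scatter_mean, "mean_primary")
    y, scale = add_poisson_noise(total_mean, target_counts, seed + 1)
    scatter_true = ProjectionSet(geom, scatter_mean * scale, "mean_scatter")
    atten_proj = project_attenuation(mu_r, geom)
    return Measurement(geom, y, scatter_true, atten_proj, mu_r, x_r, scale)


def reconstruct(
    meas: Measurement,
    scatter: ProjectionSet | None,
    cdr: CDRModel | None = None,
    cfg: OsemConfig = OsemConfig(),
) -> VoxelVolume:
    """OS-EM reconstruction of a measurement with a given scatter mean.

    The count scale is divided out so the result is in MBq per voxel.
    """
    system = SystemModel(meas.mu_recon, meas.geom, cdr or desk_cdr(), efficiency=1.0)
    x, _info = osem(meas.y, system, scatter, cfg)
    x.values /= meas.count_scale
    return x


# ---------------------------------------------------------------------------
# fixtures: the packaged desk-scale virtual-patient library


#: per-phantom (lesion volumes mL, uptake ratios) spanning the clinical range
FIXTURE_LESION_SETS = [
    ([29.6, 27.4, 21.0, 5.7], [4.0, 3.0, 5.0, 6.0]),
    ([932.1], [2.5]),
    ([41.8, 183.8], [3.5, 2.0]),
    ([56.9, 26.4], [5.0, 4.0]),
    ([21.2, 22.7, 21.7], [4.5, 3.5, 5.5]),
    ([26.9, 60.0], [3.0, 6.0]),
    ([100.0, 15.0], [2.0, 5.0]),
    ([8.0, 35.0], [6.0, 3.0]),
    ([48.0, 12.0, 30.0], [4.0, 5.0, 2.5]),
    ([70.0, 5.7], [3.0, 7.0]),
]

FIXTURE_ROLES = (
    ["scatter_train"] * 3 + ["scatter_val"]
    + ["dose_train"] * 2 + ["dose_val"]
    + ["test"] * 3
)


def make_fixtures(
    seed: int = 0,
    n: int = 10,
    out_dir: str | None = None,
    grid: VoxelGrid | None = None,
    volume_scale: float = 1.0,
) -> dict:
    """Generate the desk-scale virtual-patient library with disjoint
    train/validation/test roles for the two networks (mirroring the
    6/6/6-style discipline of splitting phantoms between stages).

    Returns a manifest; with ``out_dir`` also writes NIfTI volumes and the
    manifest JSON.  ``volume_scale`` shrinks liver and lesion volumes
    together for sub-desk grids.
    """
    grid = grid or DESK_GRID
    manifest = {"seed": seed, "phantoms": []}
    phantoms = []
    for i in range(n):
        volumes, ratios = FIXTURE_LESION_SETS[i % len(FIXTURE_LESION_SETS)]
        cfg = PhantomConfig(
            seed=seed * 1000 + i,
            grid=grid,
            liver_volume_mL=1500.0 * volume_scale,
            lesion_volumes_mL=[v * volume_scale for v in volumes],
            lesion_uptake_ratios=list(ratios),
        )
        act, den, vois = make_virtual_patient(cfg)
        role = FIXTURE_ROLES[i % len(FIXTURE_ROLES)]
        rec = {
            "id": i,
            "role": role,
            "seed": cfg.seed,
            "lesion_volumes_mL": list(cfg.lesion_volumes_mL),
            "uptake_ratios": list(ratios),
        }
        manifest["phantoms"].append(rec)
        phantoms.append((act, den, vois))
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            from .volumes import save_voiset

            save_volume(act, os.path.join(out_dir, f"phantom{i:02d}_activity.nii.gz"))
            save_volume(den, os.path.join(out_dir, f"phantom{i:02d}_density.nii.gz"))
            save_voiset(vois, os.path.join(out_dir, f"phantom{i:02d}_vois.nii.gz"))
    manifest["hash"] = config_hash(manifest)
    if out_dir:
        with open(os.path.join(out_dir, "manifest.json"), "w") as f:
            json.dump(manifest, f, indent=1)
    manifest["_phantoms"] = phantoms
    return manifest


def validate_split(manifest: dict) -> None:
    """No phantom may appear in more than one role (no test leakage)."""
    seen = {}
    for rec in manifest["phantoms"]:
        if rec["id"] in seen:
            raise ValueError(f"phantom {rec['id']} assigned twice")
        seen[rec["id"]] = rec["role"]


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    arm: str = "CNN_SC+DblurDoseNet"
    scatter_checkpoint: str | None = None
    dose_checkpoint: str | None = None
    kernel_path: str | None = None
    grid_preset: str = "desk"
    seed: int = 0
    osem_subsets: int = 4
    osem_iterations: int = 16
    mc_dose_histories: int = 300_000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")

    def hash(self) -> str:
        return config_hash(asdict(self))


def run_pipeline(
    cfg: PipelineConfig,
    meas: Measurement,
    density: VoxelVolume,
    kernel: DoseKernel | None = None,
    scatter_net: ScatterNet | None = None,
    dose_net: DoseNet | None = None,
    gt_dose: DoseRateMap | None = None,
    vois: VOISet | None = None,
) -> dict:
    """Execute stages I-III for the selected arm.

    Networks/kernels may be passed in memory or loaded from the checkpoint
    paths in the config.  Returns a dict with the intermediate artifacts, the
    final DoseRateMap, a provenance manifest, and (when GT is supplied) a
    MetricsReport.  A failing stage raises with the stage named; artifacts
    produced before the failure are written and retained.
    """
    out: dict = {"manifest": {
        "config_hash": cfg.hash(), "arm": cfg.arm, "seed": cfg.seed,
        "versions": {"numpy": np.__version__},
    }}
    ct_grid = density.grid

    def _save_vol(name, vol):
        if cfg.out_dir:
            os.makedirs(cfg.out_dir, exist_ok=True)
            save_volume(vol, os.path.join(cfg.out_dir, name))

    # Stage I: scatter estimate
    try:
        if cfg.arm == "noSC+single_stage":
            scatter = None
        else:
            net = scatter_net or load_scatter_checkpoint(cfg.scatter_checkpoint)
            scatter = predict_scatter(net, meas.y, meas.atten_proj)
            if cfg.out_dir:
                save_projections(scatter, os.path.join(cfg.out_dir, "scatter_estimate.h5"),
                                 extra={"config_hash": cfg.hash()})
        out["scatter_estimate"] = scatter
    except Exception as e:
        raise RuntimeError(f"stage I (scatter estimation) failed: {e}") from e

    # Stage II: OS-EM + resampling to the CT grid
    try:
        recon = reconstruct(meas, scatter,
                            cfg=OsemConfig(cfg.osem_subsets, cfg.osem_iterations))
        recon_ct = resample_to_ct(recon, ct_grid)
        out["recon"] = recon
        out["recon_ct"] = recon_ct
        _save_vol("recon.nii.gz", recon_ct)
    except Exception as e:
        raise RuntimeError(f"stage II (OS-EM reconstruction) failed: {e}") from e

    # Stage III: dosimetry
    try:
        kern = kernel or (load_kernel(cfg.kernel_path) if cfg.kernel_path else
                          generate_dvk(ct_grid.voxel_size_mm, seed=cfg.seed))
        dvk_map = dvk_convolve(recon_ct, kern, density)
        out["dvk"] = dvk_map
        _save_vol("dvk_dose_rate.nii.gz", dvk_map.volume)
        if cfg.arm == "CNN_SC+DVK":
            dose = dvk_map
        elif cfg.arm == "CNN_SC+MC":
            dose = mc_dose_rate(recon_ct, density, cfg.mc_dose_histories, cfg.seed)
        elif cfg.arm == "CNN_SC+DblurDoseNet":
            dnet = dose_net or load_dose_checkpoint(cfg.dose_checkpoint)
            dose, info = predict_dose(dnet, recon_ct, density, dvk_map, recon_tag="CNN_SC")
            out["manifest"]["clamped_fraction"] = info["clamped_fraction"]
        else:  # noSC+single_stage
            dnet = dose_net or load_dose_checkpoint(cfg.dose_checkpoint)
            dose, info = single_stage_variant(dnet, recon_ct, density, kern)
            out["manifest"]["clamped_fraction"] = info["clamped_fraction"]
        out["dose"] = dose
        _save_vol("dose_rate.nii.gz", dose.volume)
    except Exception as e:
        raise RuntimeError(f"stage III (dosimetry) failed: {e}") from e

    if gt_dose is not None and vois is not None:
        from .metrics import MetricsReport

        rep = MetricsReport()
        for i, les in enumerate(vois.lesions):
            rep.add_voi(f"lesion_{i}", gt_dose.volume, dose.volume, les)
        rep.add_voi("healthy_liver", gt_dose.volume, dose.volume, vois.healthy_liver)
        out["report"] = rep
    if cfg.out_dir:
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as f:
            json.dump(out["manifest"], f, indent=1)
    return out
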
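"""Stage III: residual-learning dose-rate network (deblurring dosimetry).

The network maps slice packs of the scaled reconstructed activity and the
density map to the dose-rate of the middle slice.  Architecture: the two
11-slice packs are concatenated along channels and passed to a 3-layer 3-D
convolutional feature extractor (in-plane kernel 7; axial kernel depths
5, 5, 3 by default, so the 11-slice pack collapses to one slice), then a 2-D
U-Net.  The DVK dose-rate slice is added to the U-Net output (residual
learning) and the terminal transform applies the density correction and the
inverse of the per-study activity scaling.  The residual head is
zero-initialised, so the *untrained* network reproduces DVK dosimetry
exactly; training only has to learn the difference between MC ground truth
and the DVK map, which is dominated by reconstruction blur.

Per-study activity scaling: activity is multiplied by s = NC / sum(activity)
(normalising constant NC = 1e6), and because dose is linear in activity the
DVK input and the MC labels are scaled by the same s during training; the
network output is divided by s at the end.  An internal residual scale
(RMS of the positive scaled labels) conditions the MSE for Adam.

The single-stage ablation variant shares the architecture but is trained on
no-scatter-correction reconstructions with DVK(no-SC) residuals; checkpoints
carry a variant tag and inference guards against mixing the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .beta_dose import DoseKernel, DoseRateMap, dvk_convolve
from .scatter_net import TrainConfig
from .volumes import VoxelVolume

NORMALIZING_CONSTANT = 1e6  # scaled-activity units per study
DENSITY_CUTOFF = 1.0


@dataclass(frozen=True)
class DoseNetSpec:
    pack_depth: int = 11
    extractor_depths: tuple[int, int, int] = (5, 5, 3)
    extractor_channels: tuple[int, int, int] = (32, 32, 32)
    inplane_kernel: int = 7
    unet_levels: int = 4
    unet_base_channels: int = 32

    def __post_init__(self) -> None:
        if self.pack_depth % 2 != 1:
            raise ValueError("pack depth must be odd")
        if len(self.extractor_depths) != len(self.extractor_channels):
            raise ValueError("one channel count per extractor layer")
        out_d = self.pack_depth - sum(d - 1 for d in self.extractor_depths)
        if out_d < 1:
            raise ValueError("extractor depths consume more slices than the pack holds")

    @classmethod
    def desk(cls) -> "DoseNetSpec":
        """Small preset for CPU-scale training on 128x128 desk phantoms."""
        return cls(extractor_channels=(4, 4, 8), unet_levels=3, unet_base_channels=8)


@dataclass
class ActivityScaling:
    """Per-study scale s so that s * sum(activity) = the normalizing constant."""

    normalizing_constant: float = NORMALIZING_CONSTANT

    def scale_for(self, activity: VoxelVolume) -> float:
        tot = activity.total()
        if tot <= 0:
            raise ValueError("cannot scale a zero-activity study")
        return self.normalizing_constant / tot


class _UNet2d:
    """Small 2-D U-Net: two 3x3 convs per level, 2x max-pool / bilinear up,
    skip concatenation, zero-initialised 1x1 output head."""

    def __init__(self, c_in: int, levels: int, base: int, rng: np.random.Generator):
        self.levels = levels
        w = [base * 2**l for l in range(levels + 1)]
        self.down = []
        c = c_in
        for l in range(levels):
            blk = nn.Sequential(nn.Conv2d(c, w[l], 3, rng=rng), nn.ReLU(),
                                nn.Conv2d(w[l], w[l], 3, rng=rng), nn.ReLU())
            self.down.append(blk)
            c = w[l]
        self.pools = [nn.MaxPool2() for _ in range(levels)]
        self.bottleneck = nn.Sequential(nn.Conv2d(c, w[levels], 3, rng=rng), nn.ReLU(),
                                        nn.Conv2d(w[levels], w[levels], 3, rng=rng), nn.ReLU())
        self.ups = [nn.Upsample2() for _ in range(levels)]
        self.up_blocks = []
        c = w[levels]
        for l in reversed(range(levels)):
            blk = nn.Sequential(nn.Conv2d(c + w[l], w[l], 3, rng=rng), nn.ReLU(),
                                nn.Conv2d(w[l], w[l], 3, rng=rng), nn.ReLU())
            self.up_blocks.append(blk)
            c = w[l]
        self.head = nn.Conv2d(c, 1, 1, zero_init=True)
        self.params = []
        for blk in self.down + [self.bottleneck] + self.up_blocks + [self.head]:
            self.params.extend(blk.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for l in range(self.levels):
            x = self.down[l].forward(x)
            skips.append(x)
            x = self.pools[l].forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for i, l in enumerate(reversed(range(self.levels))):
            x = self.ups[i].forward(x)
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([x, skips[l]], axis=1)
            x = self.up_blocks[i].forward(x)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.head.backward(g)
        gskips = [None] * self.levels
        for i in reversed(range(self.levels)):
            l = self.levels - 1 - i  # skip level consumed at up step i
            g = self.up_blocks[i].backward(g)
            cup = self._skip_channels[i]
            gskips[l] = g[:, cup:]
            g = self.ups[i].backward(g[:, :cup])
        g = self.bottleneck.backward(g)
        for l in reversed(range(self.levels)):
            g = self.pools[l].backward(g)
            g = self.down[l].backward(g + gskips[l])
        return g


class DoseNet:
    def __init__(self, spec: DoseNetSpec, seed: int, variant: str = "two_stage"):
        if variant not in ("two_stage", "single_stage"):
            raise ValueError("variant must be two_stage or single_stage")
        self.spec = spec
        self.seed = seed
        self.variant = variant
        self.residual_scale = 1.0  # set at train time from label statistics
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        c = 2
        for kd, ch in zip(spec.extractor_depths, spec.extractor_channels):
            layers += [nn.Conv3d(c, ch, kd, k=spec.inplane_kernel, rng=rng), nn.ReLU()]
            c = ch
        self.extractor = nn.Sequential(*layers)
        self.unet = _UNet2d(c, spec.unet_levels, spec.unet_base_channels, rng)
        self.params = self.extractor.params + self.unet.params

    def forward(
        self,
        packs: np.ndarray,        # (N, 2, pack_depth, H, W) scaled activity + density
        dvk_slice: np.ndarray,    # (N, 1, H, W) scaled DVK dose rate, middle slice
        density_slice: np.ndarray,  # (N, 1, H, W) g/cm^3
        cutoff: float = DENSITY_CUTOFF,
    ) -> np.ndarray:
        f3 = self.extractor.forward(packs)
        mid = f3.shape[2] // 2
        self._f3_shape = f3.shape
        self._mid = mid
        u = self.unet.forward(f3[:, :, mid])
        self._den_fac = np.where(density_slice >= cutoff,
                                 self.residual_scale / np.maximum(density_slice, 1e-6), 0.0)
        return dvk_slice + u * self._den_fac

    def backward(self, g: np.ndarray) -> None:
        gu = self.unet.backward(g * self._den_fac)
        g3 = np.zeros(self._f3_shape)
        g3[:, :, self._mid] = gu
        self.extractor.backward(g3)


def build_dose_net(spec: DoseNetSpec, seed: int, variant: str = "two_stage") -> DoseNet:
    return DoseNet(spec, seed, variant)


# ---------------------------------------------------------------------------
# slice packs


def make_pack(values: np.ndarray, z: int, depth: int) -> np.ndarray:
    """Axial slice pack centred on z with replicate padding at volume ends.

    ``values`` is (nx, ny, nz); the returned pack is (depth, nx, ny).
    """
    nz = values.shape[2]
    half = depth // 2
    idx = np.clip(np.arange(z - half, z + half + 1), 0, nz - 1)
    return np.transpose(values[:, :, idx], (2, 0, 1))


@dataclass
class DoseStudy:
    """One co-registered study on the CT grid."""

    activity: VoxelVolume           # reconstructed (or no-SC) activity, MBq
    density: VoxelVolume            # g/cm^3
    dvk: DoseRateMap                # DVK dose-rate map computed from `activity`
    gt: DoseRateMap | None = None   # MC dose-rate from the *true* activity map

    def __post_init__(self) -> None:
        grids = {self.activity.grid, self.density.grid, self.dvk.volume.grid}
        if self.gt is not None:
            grids.add(self.gt.volume.grid)
        if len(grids) != 1:
            raise ValueError("all study volumes must be co-registered on one grid")


def _study_samples(st: DoseStudy, spec: DoseNetSpec, scaling: ActivityScaling,
                   crop: tuple[slice, slice] | None):
    """Yield (packs, dvk_slice, density_slice, label_slice, s) per axial slice."""
    s = scaling.scale_for(st.activity)
    act = st.activity.values * s
    den = st.density.values
    dvk = st.dvk.volume.values * s
    lab = st.gt.volume.values * s if st.gt is not None else None
    nz = act.shape[2]
    cx = crop or (slice(None), slice(None))
    for z in range(nz):
        pa = make_pack(act, z, spec.pack_depth)[:, cx[0], cx[1]]
        pd = make_pack(den, z, spec.pack_depth)[:, cx[0], cx[1]]
        packs = np.stack([pa, pd])  # (2, depth, h, w)
        yield (
            packs,
            dvk[cx[0], cx[1], z][None],
            den[cx[0], cx[1], z][None],
            None if lab is None else lab[cx[0], cx[1], z][None],
            s, z,
        )


def _crop_window(studies: list[DoseStudy], size: int | None) -> tuple[slice, slice] | None:
    """Fixed in-plane window around the union of dose supports (training crop)."""
    if size is None:
        return None
    m = np.zeros(studies[0].density.grid.shape[:2], dtype=bool)
    for st in studies:
        ref = st.gt.volume.values if st.gt is not None else st.dvk.volume.values
        m |= ref.max(axis=2) > 0
    if not m.any():
        cy = cx = m.shape[0] // 2
    else:
        iy, ix = np.nonzero(m)
        cy, cx = int(iy.mean()), int(ix.mean())
    ny, nx = m.shape
    y0 = int(np.clip(cy - size // 2, 0, max(ny - size, 0)))
    x0 = int(np.clip(cx - size // 2, 0, max(nx - size, 0)))
    return slice(y0, y0 + size), slice(x0, x0 + size)


def train_dose_net(
    net: DoseNet,
    studies: list[DoseStudy],
    cfg: TrainConfig,
    crop_size: int | None = None,
    dose_slices_only: bool = True,
    slice_stride: int = 1,
) -> tuple[DoseNet, dict]:
    """Pixel-wise MSE training on dose-rate slices with best-val checkpointing.

    GT labels must come from true activity/density MC, never reconstructions.
    One study is held out for validation when more than one is given.  With
    ``dose_slices_only`` slices whose DVK slice is empty are skipped.
    """
    if not studies:
        raise ValueError("empty training dataset")
    if any(st.gt is None for st in studies):
        raise ValueError("training requires GT dose-rate labels")
    n_val = 1 if len(studies) > 1 else 0
    val = studies[len(studies) - n_val:]
    train = studies[: len(studies) - n_val] or studies
    crop = _crop_window(studies, crop_size)
    scaling = ActivityScaling()

    def collect(sts, stride=1):
        P, D, Dn, Y = [], [], [], []
        for st in sts:
            for packs, dvk_sl, den_sl, lab_sl, _s, z in _study_samples(st, net.spec, scaling, crop):
                if z % stride:
                    continue
                if dose_slices_only and dvk_sl.sum() <= 0 and lab_sl.sum() <= 0:
                    continue
                P.append(packs)
                D.append(dvk_sl)
                Dn.append(den_sl)
                Y.append(lab_sl)
        return (np.stack(P), np.stack(D), np.stack(Dn), np.stack(Y))

    Ptr, Dtr, Ntr, Ytr = collect(train, slice_stride)
    Pva, Dva, Nva, Yva = collect(val, slice_stride) if val else (Ptr, Dtr, Ntr, Ytr)

    # condition the head on the magnitude of the *needed* correction
    resid = (Ytr - Dtr)[(Ytr > 0) | (Dtr > 0)]
    net.residual_scale = float(np.sqrt((resid**2).mean())) if resid.size else 1.0

    def eval_mse(P, D, N_, Y, bs=8):
        tot, cnt = 0.0, 0
        for i in range(0, P.shape[0], bs):
            pred = net.forward(P[i:i + bs], D[i:i + bs], N_[i:i + bs])
            tot += float(((pred - Y[i:i + bs]) ** 2).sum())
            cnt += Y[i:i + bs].size
        return tot / cnt

    opt = nn.Adam(net.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    dvk_baseline = float(((Dva - Yva) ** 2).mean())  # zero-residual network
    history = {"train_mse": [], "val_mse": [eval_mse(Pva, Dva, Nva, Yva)],
               "dvk_baseline_val_mse": dvk_baseline}
    best = (history["val_mse"][0], nn.get_state(net.params))
    n = Ptr.shape[0]
    for _ep in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            opt.zero_grad()
            pred = net.forward(Ptr[sel], Dtr[sel], Ntr[sel])
            loss, g = nn.mse(pred, Ytr[sel])
            net.backward(g)
            if cfg.learning_rate > 0:
                opt.step()
            ep_loss += loss
            nb += 1
        history["train_mse"].append(ep_loss / nb)
        vm = eval_mse(Pva, Dva, Nva, Yva)
        history["val_mse"].append(vm)
        if vm < best[0]:
            best = (vm, nn.get_state(net.params))
    nn.set_state(net.params, best[1])
    history["best_val_mse"] = best[0]
    return net, history


def predict_dose(
    net: DoseNet,
    activity: VoxelVolume,
    density: VoxelVolume,
    dvk_map: DoseRateMap,
    recon_tag: str | None = None,
    batch: int = 8,
) -> tuple[DoseRateMap, dict]:
    """Slice-by-slice volume inference; negatives clamped to 0 (logged).

    ``recon_tag`` ('CNN_SC' or 'no_SC') guards against feeding a
    scatter-corrected reconstruction to a single-stage checkpoint and vice
    versa.
    """
    if density is None:
        raise ValueError("density volume is required")
    if net.variant == "single_stage" and recon_tag == "CNN_SC":
        raise ValueError("single-stage checkpoint expects a no-SC reconstruction")
    if net.variant == "two_stage" and recon_tag == "no_SC":
        raise ValueError("two-stage checkpoint expects a scatter-corrected reconstruction")
    st = DoseStudy(activity=activity, density=density, dvk=dvk_map)
    scaling = ActivityScaling()
    s = scaling.scale_for(activity)
    nz = activity.grid.shape[2]
    out = np.zeros(activity.grid.shape)
    samples = list(_study_samples(st, net.spec, scaling, None))
    for i in range(0, nz, batch):
        chunk = samples[i:i + batch]
        P = np.stack([c[0] for c in chunk])
        D = np.stack([c[1] for c in chunk])
        N_ = np.stack([c[2] for c in chunk])
        pred = net.forward(P, D, N_)
        for j, c in enumerate(chunk):
            out[:, :, c[5]] = pred[j, 0]
    out /= s
    neg = out < 0
    clamped_fraction = float(neg.mean())
    out = np.maximum(out, 0.0)
    vol = VoxelVolume(activity.grid, out, "dose_rate_nGy_per_s")
    return DoseRateMap(vol, "network"), {"clamped_fraction": clamped_fraction}


def single_stage_variant(
    net: DoseNet,
    no_sc_recon: VoxelVolume,
    density: VoxelVolume,
    kernel: DoseKernel,
) -> tuple[DoseRateMap, dict]:
    """Ablation: one network does scatter handling + dosimetry in one shot.

    The DVK residual input is computed from the *no-SC* reconstruction.
    """
    dvk_map = dvk_convolve(no_sc_recon, kernel, density)
    return predict_dose(net, no_sc_recon, density, dvk_map, recon_tag="no_SC")


# ---------------------------------------------------------------------------
# checkpoints


def save_dose_checkpoint(net: DoseNet, path: str, extra: dict | None = None) -> None:
    arrays = {f"p{i}": p[0] for i, p in enumerate(net.params)}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    side = {
        "kind": "dose_net",
        "spec": asdict(net.spec),
        "seed": net.seed,
        "variant": net.variant,
        "residual_scale": net.residual_scale,
        "normalizing_constant": NORMALIZING_CONSTANT,
    }
    side.update(extra or {})
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as f:
        json.dump(side, f, indent=1)


def load_dose_checkpoint(path: str) -> DoseNet:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as f:
        side = json.load(f)
    spec = side["spec"]
    spec["extractor_depths"] = tuple(spec["extractor_depths"])
    spec["extractor_channels"] = tuple(spec["extractor_channels"])
    net = DoseNet(DoseNetSpec(**spec), side["seed"], side["variant"])
    net.residual_scale = side["residual_scale"]
    with np.load(base + ".npz") as z:
        nn.set_state(net.params, [z[f"p{i}"] for i in range(len(net.params))])
    return net
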
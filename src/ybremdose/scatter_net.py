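"""Stage I: per-view CNN estimation of bremsstrahlung scatter projections.

Two input branches — one for the scaled measured (total) projection, one for
the projected attenuation map — of three 3x3 conv + ReLU layers each; the
branch outputs are concatenated along channels and passed through a
three-layer conv trunk, a pointwise (1x1) convolution and a terminal ReLU,
so the scatter estimate is non-negative by construction and every layer
preserves the spatial size.  Views are processed independently.

Input scaling: each study's total projection and its ground-truth scatter
label are divided by (study total counts x 1e-4); the attenuation line
integrals (O(1-10)) are divided by 10.  The constants are stored with the
checkpoint and inverted at the output.  Training minimises pixel-wise MSE
against MC scatter labels with Adam; the paper-scale recipe (lr 1e-4,
800 epochs) is stored as the "paper" preset, the desk preset uses lr 1e-3
and 200 epochs on the packaged synthetic fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .projector import ProjectionGeometry, ProjectionSet

ATTEN_SCALE = 10.0
COUNT_SCALE = 1e-4


@dataclass(frozen=True)
class ScatterNetSpec:
    branch_layers: int = 3
    trunk_layers: int = 3
    branch_channels: int = 16
    trunk_channels: int = 32
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.branch_layers < 1 or self.trunk_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd to preserve spatial size")

    @classmethod
    def desk(cls) -> "ScatterNetSpec":
        """Narrower preset for CPU-scale training."""
        return cls(branch_channels=8, trunk_channels=16)


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    validation_fraction: float = 0.25  # one phantom of four held out

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    @classmethod
    def paper_scatter(cls) -> "TrainConfig":
        return cls(learning_rate=1e-4, epochs=800, batch_size=32)

    @classmethod
    def paper_dose(cls) -> "TrainConfig":
        return cls(learning_rate=1e-3, epochs=300, batch_size=32)


class ScatterNet:
    """Two-branch scatter CNN operating on (1, H, W) view images."""

    def __init__(self, spec: ScatterNetSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)

        def branch() -> nn.Sequential:
            layers: list[nn.Layer] = []
            c = 1
            for _ in range(spec.branch_layers):
                layers += [nn.Conv2d(c, spec.branch_channels, spec.kernel, rng=rng), nn.ReLU()]
                c = spec.branch_channels
            return nn.Sequential(*layers)

        self.branch_total = branch()
        self.branch_atten = branch()
        trunk: list[nn.Layer] = []
        c = 2 * spec.branch_channels
        for _ in range(spec.trunk_layers):
            trunk += [nn.Conv2d(c, spec.trunk_channels, spec.kernel, rng=rng), nn.ReLU()]
            c = spec.trunk_channels
        head = nn.Conv2d(c, 1, 1, rng=rng)
        head.params[1][0][...] = 0.1  # start the terminal ReLU alive
        trunk += [head, nn.ReLU()]
        self.trunk = nn.Sequential(*trunk)
        self.params = (self.branch_total.params + self.branch_atten.params
                       + self.trunk.params)

    def forward(self, total: np.ndarray, atten: np.ndarray) -> np.ndarray:
        if total.shape != atten.shape:
            raise ValueError("branch inputs must share one spatial size")
        a = self.branch_total.forward(total)
        b = self.branch_atten.forward(atten)
        self._c = a.shape[1]
        return self.trunk.forward(np.concatenate([a, b], axis=1))

    def backward(self, g: np.ndarray) -> None:
        gc = self.trunk.backward(g)
        self.branch_total.backward(gc[:, : self._c])
        self.branch_atten.backward(gc[:, self._c:])


def build_scatter_net(spec: ScatterNetSpec, seed: int) -> ScatterNet:
    return ScatterNet(spec, seed)


@dataclass
class ScatterStudy:
    """One study: total measured counts, attenuation projection, optional GT."""

    total: ProjectionSet
    atten: ProjectionSet
    scatter_gt: ProjectionSet | None = None

    def scaled_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, float]:
        s = self.total.total() * COUNT_SCALE
        if s <= 0:
            raise ValueError("study has zero total counts")
        x1 = (self.total.values / s)[:, None]
        x2 = (self.atten.values / ATTEN_SCALE)[:, None]
        y = (self.scatter_gt.values / s)[:, None] if self.scatter_gt is not None else None
        return x1, x2, y, s


def _dataset_mse(net: ScatterNet, studies: list[ScatterStudy], batch: int = 16) -> float:
    tot, cnt = 0.0, 0
    for st in studies:
        x1, x2, y, _s = st.scaled_arrays()
        for i in range(0, x1.shape[0], batch):
            pred = net.forward(x1[i:i + batch], x2[i:i + batch])
            tot += float(((pred - y[i:i + batch]) ** 2).sum())
            cnt += y[i:i + batch].size
    return tot / cnt


def train_scatter_net(
    net: ScatterNet,
    studies: list[ScatterStudy],
    cfg: TrainConfig,
) -> tuple[ScatterNet, dict]:
    """Train on per-view samples; one study is held out for validation.

    Returns the net with the best-validation parameters restored, plus a
    history dict with per-epoch train/validation MSE (epoch 0 = untrained).
    """
    if not studies:
        raise ValueError("empty training dataset")
    if any(st.scatter_gt is None for st in studies):
        raise ValueError("all training studies need GT scatter labels")
    n_val = max(1, int(round(cfg.validation_fraction * len(studies)))) if len(studies) > 1 else 0
    val = studies[len(studies) - n_val:]
    train = studies[: len(studies) - n_val] or studies

    X1, X2, Y = [], [], []
    for st in train:
        x1, x2, y, _ = st.scaled_arrays()
        X1.append(x1)
        X2.append(x2)
        Y.append(y)
    X1, X2, Y = np.concatenate(X1), np.concatenate(X2), np.concatenate(Y)

    opt = nn.Adam(net.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_mse": [], "val_mse": []}
    val_ref = val or train
    best = (np.inf, nn.get_state(net.params))
    v0 = _dataset_mse(net, val_ref)
    history["val_mse"].append(v0)
    if v0 < best[0]:
        best = (v0, nn.get_state(net.params))
    n = X1.shape[0]
    for _ep in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            opt.zero_grad()
            pred = net.forward(X1[sel], X2[sel])
            loss, g = nn.mse(pred, Y[sel])
            net.backward(g)
            if cfg.learning_rate > 0:
                opt.step()
            ep_loss += loss
            nb += 1
        history["train_mse"].append(ep_loss / nb)
        vm = _dataset_mse(net, val_ref)
        history["val_mse"].append(vm)
        if vm < best[0]:
            best = (vm, nn.get_state(net.params))
    nn.set_state(net.params, best[1])
    history["best_val_mse"] = best[0]
    return net, history


def predict_scatter(
    net: ScatterNet, total: ProjectionSet, atten: ProjectionSet
) -> ProjectionSet:
    """Scatter-mean estimate in count units, one view at a time-independent pass."""
    if total.values.shape[1:] != atten.values.shape[1:]:
        raise ValueError("total and attenuation projections must share spatial size")
    st = ScatterStudy(total=total, atten=atten)
    x1, x2, _y, s = st.scaled_arrays()
    pred = net.forward(x1, x2)[:, 0] * s
    return ProjectionSet(total.geometry, np.maximum(pred, 0.0), "mean_scatter")


# ---------------------------------------------------------------------------
# checkpointing: npz weights + JSON sidecar


def save_scatter_checkpoint(net: ScatterNet, path: str, extra: dict | None = None) -> None:
    arrays = {f"p{i}": p[0] for i, p in enumerate(net.params)}
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    side = {
        "kind": "scatter_net",
        "spec": asdict(net.spec),
        "seed": net.seed,
        "atten_scale": ATTEN_SCALE,
        "count_scale": COUNT_SCALE,
    }
    side.update(extra or {})
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as f:
        json.dump(side, f, indent=1)


def load_scatter_checkpoint(path: str) -> ScatterNet:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as f:
        side = json.load(f)
    net = ScatterNet(ScatterNetSpec(**side["spec"]), side["seed"])
    with np.load(base + ".npz") as z:
        nn.set_state(net.params, [z[f"p{i}"] for i in range(len(net.params))])
    return net
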
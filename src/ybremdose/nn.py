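"""Minimal NumPy layer engine with manual backprop for the two small CNNs.

Supports exactly what the scatter-estimation network and the residual
dosimetry network need: 2-D and 3-D convolutions (im2col + BLAS matmul),
ReLU, 2x max-pooling, bilinear 2x upsampling, channel concatenation, MSE
loss and the Adam optimizer.  Data layout is (N, C, H, W) for 2-D and
(N, C, D, H, W) for 3-D tensors; dtype float64 throughout, and everything is
deterministic given the initialization seed.
"""

from __future__ import annotations

import numba
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@numba.njit(cache=True, fastmath=True)
def _conv3d_fwd(xp, W, b, out):  # pragma: no cover - exercised via Conv3d
    n_, co_, do_, h_, w_ = out.shape
    ci_, kd_, k_, _ = W.shape[1:]
    for n in range(n_):
        for d in range(do_):
            for ci in range(ci_):
                for t in range(kd_):
                    for i in range(k_):
                        for j in range(k_):
                            for co in range(co_):
                                wv = W[co, ci, t, i, j]
                                for h in range(h_):
                                    for w in range(w_):
                                        out[n, co, d, h, w] += wv * xp[n, ci, d + t, h + i, w + j]
    for n in range(n_):
        for co in range(co_):
            for d in range(do_):
                for h in range(h_):
                    for w in range(w_):
                        out[n, co, d, h, w] += b[co]


@numba.njit(cache=True, fastmath=True)
def _conv3d_bwd(xp, W, g, gxp, gW, gb):  # pragma: no cover - exercised via Conv3d
    n_, co_, do_, h_, w_ = g.shape
    ci_, kd_, k_, _ = W.shape[1:]
    for n in range(n_):
        for co in range(co_):
            for d in range(do_):
                for h in range(h_):
                    for w in range(w_):
                        gb[co] += g[n, co, d, h, w]
    for n in range(n_):
        for d in range(do_):
            for ci in range(ci_):
                for t in range(kd_):
                    for i in range(k_):
                        for j in range(k_):
                            for co in range(co_):
                                gwv = 0.0
                                wv = W[co, ci, t, i, j]
                                for h in range(h_):
                                    for w in range(w_):
                                        gv = g[n, co, d, h, w]
                                        gwv += gv * xp[n, ci, d + t, h + i, w + j]
                                        gxp[n, ci, d + t, h + i, w + j] += gv * wv
                                gW[co, ci, t, i, j] += gwv


class Layer:
    params: list  # list of [value, grad] pairs

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2-D convolution (k x k kernel, zero padding (k-1)/2)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = np.zeros((c_out, c_in, k, k)) if zero_init else \
            rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)
        b = np.zeros(c_out)
        self.params = [[w, np.zeros_like(w)], [b, np.zeros_like(b)]]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        self._cols = cols
        W = self.params[0][0].reshape(self.c_out, -1)
        out = cols @ W.T + self.params[1][0]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        p, k = self.pad, self.k
        gf = g.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.params[0][1] += (gf.T @ self._cols).reshape(self.params[0][0].shape)
        self.params[1][1] += gf.sum(axis=0)
        W = self.params[0][0].reshape(self.c_out, -1)
        gcols = (gf @ W).reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + h, j:j + w] += gcols[:, :, :, :, i, j]
        return gx[:, :, p:p + h, p:p + w]


class Conv3d(Layer):
    """3-D convolution, same-padded in-plane, *valid* along depth.

    Kernel (kd, k, k): depth shrinks by kd - 1, the in-plane size is kept.
    Used by the slice-pack feature extractor.
    """

    def __init__(self, c_in: int, c_out: int, kd: int, k: int = 7,
                 rng: np.random.Generator | None = None, impl: str = "direct"):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("in-plane kernel size must be odd")
        if impl not in ("direct", "im2col"):
            raise ValueError("impl must be 'direct' or 'im2col'")
        self.c_in, self.c_out, self.kd, self.k = c_in, c_out, kd, k
        self.pad = (k - 1) // 2
        self.impl = impl
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kd * k * k
        w = rng.standard_normal((c_out, c_in, kd, k, k)) * np.sqrt(2.0 / fan_in)
        b = np.zeros(c_out)
        self.params = [[w, np.zeros_like(w)], [b, np.zeros_like(b)]]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        self._shape = x.shape
        p = self.pad
        do = d - self.kd + 1
        if do < 1:
            raise ValueError(f"depth {d} too small for kernel depth {self.kd}")
        xp = np.ascontiguousarray(np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p), (p, p))))
        if self.impl == "direct":
            xp32 = xp.astype(np.float32)
            self._xp = xp32
            out = np.zeros((n, self.c_out, do, h, w), dtype=np.float32)
            _conv3d_fwd(xp32, self.params[0][0].astype(np.float32),
                        self.params[1][0].astype(np.float32), out)
            return out.astype(np.float64)
        cols = sliding_window_view(xp, (self.kd, self.k, self.k), axis=(2, 3, 4))
        cols = cols.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n * do * h * w, c * self.kd * self.k * self.k)
        self._cols = cols
        W = self.params[0][0].reshape(self.c_out, -1)
        out = cols @ W.T + self.params[1][0]
        return out.reshape(n, do, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        p, k, kd = self.pad, self.k, self.kd
        do = d - kd + 1
        if self.impl == "direct":
            gxp = np.zeros_like(self._xp)
            g32 = np.ascontiguousarray(g, dtype=np.float32)
            gW = np.zeros(self.params[0][0].shape, dtype=np.float32)
            gb = np.zeros(self.params[1][0].shape, dtype=np.float32)
            _conv3d_bwd(self._xp, self.params[0][0].astype(np.float32), g32, gxp, gW, gb)
            self.params[0][1] += gW.astype(np.float64)
            self.params[1][1] += gb.astype(np.float64)
            return gxp[:, :, :, p:p + h, p:p + w].astype(np.float64)
        gf = g.transpose(0, 2, 3, 4, 1).reshape(n * do * h * w, self.c_out)
        self.params[0][1] += (gf.T @ self._cols).reshape(self.params[0][0].shape)
        self.params[1][1] += gf.sum(axis=0)
        W = self.params[0][0].reshape(self.c_out, -1)
        gcols = (gf @ W).reshape(n, do, h, w, c, kd, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        gx = np.zeros((n, c, d, h + 2 * p, w + 2 * p))
        for t in range(kd):
            for i in range(k):
                for j in range(k):
                    gx[:, :, t:t + do, i:i + h, j:j + w] += gcols[:, :, :, :, :, t, i, j]
        return gx[:, :, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling (requires even spatial size)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # ties route the gradient to a single winner (first in scan order)
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        flat &= first
        self._mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gx = self._mask * g[:, :, :, None, :, None]
        return gx.reshape(n, c, h, w)


def _upsample_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense bilinear x2 upsampling matrix (align-corners-false convention)."""
    U = np.zeros((n_out, n_in))
    for i in range(n_out):
        s = (i + 0.5) / 2.0 - 0.5
        j0 = int(np.floor(s))
        f = s - j0
        for j, w in ((j0, 1.0 - f), (j0 + 1, f)):
            U[i, min(max(j, 0), n_in - 1)] += w
    return U


class Upsample2(Layer):
    """Bilinear 2x upsampling."""

    _cache: dict[int, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._hw = (h, w)
        Uh = self._get(h)
        Uw = self._get(w)
        t = np.einsum("ij,ncjk->ncik", Uh, x)
        return np.einsum("kl,ncil->ncik", Uw, t)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        Uh = self._get(h)
        Uw = self._get(w)
        t = np.einsum("ij,ncik->ncjk", Uh, g)
        return np.einsum("kl,ncjk->ncjl", Uw, t)

    @classmethod
    def _get(cls, n: int) -> np.ndarray:
        if n not in cls._cache:
            cls._cache[n] = _upsample_matrix(2 * n, n)
        return cls._cache[n]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)
        for lay in self.layers:
            self.params.extend(lay.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p[1][...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p[...] = p - self.lr * mh / (np.sqrt(vh) + self.eps)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Pixel-wise mean square error and its gradient wrt pred."""
    diff = pred - target
    return float((diff**2).mean()), 2.0 * diff / diff.size


def get_state(params: list) -> list[np.ndarray]:
    return [p[0].copy() for p in params]


def set_state(params: list, state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p[0][...] = s
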
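"""Minimal CPU conv-net engine for small 3D detection models.

Layers operate on single samples shaped ``(C, D, H, W)`` in float32 and
implement explicit forward/backward passes; convolutions are evaluated as
im2col + BLAS matmul, which is the fastest portable route for the small
channel widths this package uses.  Each layer instance caches the state of
its last forward call, so a layer object must appear exactly once in a
model graph (weight sharing across call sites is deliberately unsupported).

Optimizers implement the Ranger recipe used for training the detector:
RAdam combined with Lookahead, with optional gradient centralization on
convolution weights.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: sub-classes define forward/backward and list params."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv3d(Module):
    """3D convolution, kernel 1 or 3, stride 1 or 2, optional channel groups.

    Weight is stored flat as ``(out_channels, in_per_group * k^3)`` with the
    output channels of each group contiguous.  Padding is ``k // 2`` (shape-
    preserving at stride 1).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}"
            )
        self.cin, self.cout, self.k, self.stride, self.groups = (
            in_channels, out_channels, kernel, stride, groups)
        self.pad = kernel // 2
        fan_in = (in_channels // groups) * kernel ** 3
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (out_channels, fan_in), fan_in), "conv_w")
        self.bias = Param(np.zeros(out_channels), "conv_b") if bias else None
        self._cache: tuple | None = None

    def _im2col(self, xp: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]
        c, do, ho, wo = win.shape[:4]
        col = np.ascontiguousarray(
            win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(do * ho * wo, c * k ** 3)
        return col, (do, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        g = self.groups
        cin_g, cout_g = self.cin // g, self.cout // g
        if self.k == 1 and self.stride == 1:
            d, h, w = x.shape[1:]
            xf = x.reshape(self.cin, -1)
            y = np.empty((self.cout, d * h * w), dtype=F32)
            for i in range(g):
                y[i * cout_g:(i + 1) * cout_g] = (
                    self.weight.data[i * cout_g:(i + 1) * cout_g]
                    @ xf[i * cin_g:(i + 1) * cin_g])
            y = y.reshape(self.cout, d, h, w)
            self._cache = (xf, (d, h, w), None)
        else:
            p = self.pad
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
            cols = []
            ys = []
            for i in range(g):
                col, oshape = self._im2col(xp[i * cin_g:(i + 1) * cin_g])
                w_g = self.weight.data[i * cout_g:(i + 1) * cout_g]
                ys.append(col @ w_g.T)
                cols.append(col)
            do, ho, wo = oshape
            y = np.concatenate(ys, axis=1).T.reshape(self.cout, do, ho, wo)
            self._cache = (cols, oshape, x.shape)
        if self.bias is not None:
            y += self.bias.data[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.asarray(dy, dtype=F32)
        g = self.groups
        cin_g, cout_g = self.cin // g, self.cout // g
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(1, 2, 3))
        if self.k == 1 and self.stride == 1:
            xf, (d, h, w), _ = self._cache
            dyf = dy.reshape(self.cout, -1)
            dx = np.empty((self.cin, d * h * w), dtype=F32)
            for i in range(g):
                sl_o = slice(i * cout_g, (i + 1) * cout_g)
                sl_i = slice(i * cin_g, (i + 1) * cin_g)
                self.weight.grad[sl_o] += dyf[sl_o] @ xf[sl_i].T
                dx[sl_i] = self.weight.data[sl_o].T @ dyf[sl_o]
            return dx.reshape(self.cin, d, h, w)
        cols, (do, ho, wo), xshape = self._cache
        k, s, p = self.k, self.stride, self.pad
        n = do * ho * wo
        dyf = dy.reshape(self.cout, n)
        dxp = np.zeros(
            (self.cin, xshape[1] + 2 * p, xshape[2] + 2 * p, xshape[3] + 2 * p), dtype=F32)
        for i in range(g):
            sl_o = slice(i * cout_g, (i + 1) * cout_g)
            dy_g = dyf[sl_o].T  # (n, cout_g)
            self.weight.grad[sl_o] += dy_g.T @ cols[i]
            dcol = (dy_g @ self.weight.data[sl_o]).reshape(do, ho, wo, cin_g, k, k, k)
            target = dxp[i * cin_g:(i + 1) * cin_g]
            for kz in range(k):
                for ky in range(k):
                    for kx in range(k):
                        target[:, kz:kz + s * do:s, ky:ky + s * ho:s, kx:kx + s * wo:s] += (
                            dcol[:, :, :, :, kz, ky, kx].transpose(3, 0, 1, 2))
        if p:
            return dxp[:, p:-p, p:-p, p:-p]
        return dxp


class GroupNorm(Module):
    """Batch-independent normalization over channel groups."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5) -> None:
        while channels % groups:
            groups -= 1
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Param(np.ones(channels), "gn_gamma")
        self.beta = Param(np.zeros(channels), "gn_beta")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        shp = x.shape
        xg = x.reshape(self.groups, -1)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(shp)
        self._cache = (xhat, inv, shp)
        return self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shp = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = (dy * self.gamma.data[:, None, None, None]).reshape(self.groups, -1)
        xh = xhat.reshape(self.groups, -1)
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xh).mean(axis=1, keepdims=True)
        dx = inv * (dxhat - m1 - xh * m2)
        return dx.reshape(shp).astype(F32)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class Upsample2(Module):
    """Nearest-neighbour x2 upsampling in all three spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = dy.shape
        return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def centralize_gradient(grad: np.ndarray) -> np.ndarray:
    """Subtract the per-filter mean from a multi-axis gradient.

    Applied to weights with ndim > 1 (convolution kernels); vectors (biases,
    norm parameters) pass through unchanged.
    """
    if grad.ndim > 1:
        return grad - grad.mean(axis=tuple(range(1, grad.ndim)), keepdims=True)
    return grad


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_centralization: bool = False) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.gc = grad_centralization
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = centralize_gradient(p.grad) if self.gc else p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RAdam:
    """Rectified Adam: warms up the adaptive term by tracking the SMA length."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_centralization: bool = True) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.gc = grad_centralization
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        rho_inf = 2.0 / (1.0 - b2) - 1.0
        b2t = b2 ** self.t
        rho = rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        for i, p in enumerate(self.params):
            g = centralize_gradient(p.grad) if self.gc else p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            if rho > 4.0:
                r = math.sqrt(((rho - 4) * (rho - 2) * rho_inf)
                              / ((rho_inf - 4) * (rho_inf - 2) * rho))
                vhat = np.sqrt(self.v[i] / (1 - b2t))
                p.data -= self.lr * r * mhat / (vhat + self.eps)
            else:
                p.data -= self.lr * mhat


class Lookahead:
    """Lookahead wrapper: every k steps, slow weights move toward fast weights."""

    def __init__(self, inner: Adam | RAdam, k: int = 6, alpha: float = 0.5) -> None:
        self.inner = inner
        self.k, self.alpha = k, alpha
        self.slow = [p.data.copy() for p in inner.params]
        self._step = 0

    def step(self) -> None:
        self.inner.step()
        self._step += 1
        if self._step % self.k == 0:
            for s, p in zip(self.slow, self.inner.params):
                s += self.alpha * (p.data - s)
                p.data[...] = s


def make_ranger(params: Sequence[Param], lr: float = 1e-3,
                grad_centralization: bool = True,
                lookahead_k: int = 6, lookahead_alpha: float = 0.5) -> Lookahead:
    """Ranger optimizer: RAdam + Lookahead with gradient centralization."""
    return Lookahead(RAdam(params, lr=lr, grad_centralization=grad_centralization),
                     k=lookahead_k, alpha=lookahead_alpha)
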
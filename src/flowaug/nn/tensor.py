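"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the flow-regression U-Nets need: 3D
convolution (kernel 3, stride 1, zero padding 1), leaky ReLU, 2x average
pooling, 2x nearest-neighbour upsampling, channel concatenation, a
differentiable trilinear warp layer, and a mean-squared-error loss.  Each
op records a backward closure; `Tensor.backward()` runs the tape in
reverse topological order.  All data are float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv3d",
    "leaky_relu",
    "avg_pool2",
    "upsample2",
    "concat",
    "warp_volume",
    "grad_penalty",
    "add_scaled",
    "mse_loss",
    "Adam",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()

    def zero_grad(self):
        self.grad = None


def _im2col(arr: np.ndarray) -> np.ndarray:
    """(N, C, D, H, W) -> (N, D*H*W, C*27) patch matrix, zero padding 1."""
    n, c, d, h, w = arr.shape
    xp = np.pad(arr, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))  # (N,C,D,H,W,3,3,3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        n, d * h * w, c * 27
    )


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D convolution, kernel 3x3x3, stride 1, zero padding 1.

    x: (N, Cin, D, H, W); w: (Cout, Cin, 3, 3, 3); b: (Cout,)

    The input gradient is computed as a transposed convolution (correlation
    of the output gradient with the spatially flipped, channel-transposed
    kernel) through the same im2col path, avoiding a scatter loop.
    """
    n, cin, d, h, wd = x.shape
    cout = w.shape[0]
    col = _im2col(x.data)
    w2 = w.data.reshape(cout, cin * 27)
    out = np.einsum("npc,kc->nkp", col, w2, optimize=True)  # (N, Cout, DHW)
    y = Tensor(
        out.reshape(n, cout, d, h, wd) + b.data[None, :, None, None, None],
        parents=(x, w, b),
    )

    def _backward():
        gy = y.grad.reshape(n, cout, d * h * wd)  # (N, Cout, DHW)
        if w.requires_grad:
            gw = np.einsum("npc,nkp->kc", col, gy, optimize=True)
            w._accumulate(gw.reshape(cout, cin, 3, 3, 3))
        if b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2)))
        if x.requires_grad:
            # w_t[cin, cout, ...] = w[cout, cin, ::-1, ::-1, ::-1]
            w_t = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            gcol = _im2col(y.grad)
            gx = np.einsum("npc,kc->nkp", gcol, w_t.reshape(cin, cout * 27), optimize=True)
            x._accumulate(gx.reshape(n, cin, d, h, wd))

    y._backward = _backward
    return y


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    y = Tensor(np.where(mask, x.data, alpha * x.data), parents=(x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(np.where(mask, y.grad, alpha * y.grad))

    y._backward = _backward
    return y


def avg_pool2(x: Tensor) -> Tensor:
    """2x average pooling over all three spatial axes (dims must be even)."""
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    y = Tensor(r.mean(axis=(3, 5, 7)), parents=(x,))

    def _backward():
        if x.requires_grad:
            g = np.broadcast_to(
                y.grad[:, :, :, None, :, None, :, None] / 8.0,
                (n, c, d // 2, 2, h // 2, 2, w // 2, 2),
            )
            x._accumulate(g.reshape(n, c, d, h, w))

    y._backward = _backward
    return y


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling over the three spatial axes."""
    n, c, d, h, w = x.shape
    y = Tensor(
        np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4),
        parents=(x,),
    )

    def _backward():
        if x.requires_grad:
            g = y.grad.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
            x._accumulate(g)

    y._backward = _backward
    return y


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.shape[1]
    y = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(y.grad[:, :ca])
        if b.requires_grad:
            b._accumulate(y.grad[:, ca:])

    y._backward = _backward
    return y


def warp_volume(vol: np.ndarray, u: Tensor) -> Tensor:
    """Differentiable trilinear pull-warp of fixed volumes by predicted fields.

    vol: (N, D, H, W) constant source magnitudes; u: Tensor (N, 3, D, H, W)
    of displacements (dz, dy, dx) in voxel units.  Samples with border
    clamping; the gradient with respect to u is the analytic trilinear
    spatial derivative, zeroed where a coordinate was clamped.
    """
    n, d, h, w = vol.shape
    base = np.indices((d, h, w), dtype=np.float32)
    coords = base[None] + u.data  # (N, 3, D, H, W)
    dims = np.array([d, h, w], dtype=np.float32).reshape(1, 3, 1, 1, 1)
    inb = (coords >= 0.0) & (coords <= dims - 1.0)
    cc = np.clip(coords, 0.0, dims - 1.0)
    f = np.floor(cc)
    # keep f+1 in range: at the top edge step back one cell
    f = np.minimum(f, dims - 2.0) if min(d, h, w) > 1 else f
    t = cc - f  # fractional part, (N,3,D,H,W)
    f = f.astype(np.int64)
    z0, y0, x0 = f[:, 0], f[:, 1], f[:, 2]
    tz, ty, tx = t[:, 0], t[:, 1], t[:, 2]
    nidx = np.arange(n)[:, None, None, None]

    def gather(dz, dy, dx):
        return vol[nidx, z0 + dz, y0 + dy, x0 + dx]

    v000, v001 = gather(0, 0, 0), gather(0, 0, 1)
    v010, v011 = gather(0, 1, 0), gather(0, 1, 1)
    v100, v101 = gather(1, 0, 0), gather(1, 0, 1)
    v110, v111 = gather(1, 1, 0), gather(1, 1, 1)

    c00 = v000 * (1 - tx) + v001 * tx
    c01 = v010 * (1 - tx) + v011 * tx
    c10 = v100 * (1 - tx) + v101 * tx
    c11 = v110 * (1 - tx) + v111 * tx
    c0 = c00 * (1 - ty) + c01 * ty
    c1 = c10 * (1 - ty) + c11 * ty
    out = c0 * (1 - tz) + c1 * tz
    y = Tensor(out[:, None], parents=(u,))

    def _backward():
        if not u.requires_grad:
            return
        gy = y.grad[:, 0]
        dz_ = (c1 - c0)
        dy_ = ((c01 - c00) * (1 - tz) + (c11 - c10) * tz)
        dx_ = (
            (v001 - v000) * (1 - ty) * (1 - tz)
            + (v011 - v010) * ty * (1 - tz)
            + (v101 - v100) * (1 - ty) * tz
            + (v111 - v110) * ty * tz
        )
        g = np.stack([dz_, dy_, dx_], axis=1) * gy[:, None]
        u._accumulate(np.where(inb, g, 0.0))

    y._backward = _backward
    return y


def grad_penalty(u: Tensor) -> Tensor:
    """Smoothness penalty: mean squared forward difference of a field over
    the three spatial axes (a diffusion regularizer on predicted flows)."""
    n, c, d, h, w = u.shape
    diffs = [
        u.data[:, :, 1:] - u.data[:, :, :-1],
        u.data[:, :, :, 1:] - u.data[:, :, :, :-1],
        u.data[:, :, :, :, 1:] - u.data[:, :, :, :, :-1],
    ]
    val = sum(float((dd ** 2).mean()) for dd in diffs)
    y = Tensor(np.array(val, dtype=np.float32), parents=(u,))

    def _backward():
        if not u.requires_grad:
            return
        g = np.zeros_like(u.data)
        for ax, dd in enumerate(diffs, start=2):
            scale = 2.0 / dd.size * y.grad
            sl_hi = [slice(None)] * 5
            sl_lo = [slice(None)] * 5
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            g[tuple(sl_hi)] += scale * dd
            g[tuple(sl_lo)] -= scale * dd
        u._accumulate(g)

    y._backward = _backward
    return y


def add_scaled(a: Tensor, b: Tensor, weight: float) -> Tensor:
    """Scalar combination ``a + weight * b`` (for composite losses)."""
    y = Tensor(a.data + weight * b.data, parents=(a, b))

    def _backward():
        if a.requires_grad:
            a._accumulate(y.grad)
        if b.requires_grad:
            b._accumulate(weight * y.grad)

    y._backward = _backward
    return y


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target.astype(np.float32)
    y = Tensor(np.array((diff ** 2).mean(), dtype=np.float32), parents=(pred,))

    def _backward():
        if pred.requires_grad:
            pred._accumulate((2.0 / diff.size) * diff * y.grad)

    y._backward = _backward
    return y


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
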
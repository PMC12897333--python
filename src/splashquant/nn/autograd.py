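"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations a one-stage convolutional
detector needs: grouped 2-D convolution, batch normalization, SiLU /
sigmoid / ReLU gates, max / average pooling, nearest-neighbour
upsampling, concatenation, batched matmul and softmax (for the
position-sensitive attention block), plus the reductions used by the
detection loss.  Tensors carry float32 data; gradients are accumulated
in float32 as well.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- construction helper ---------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- elementwise ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.shape))

        return Tensor._make(self.data - other.data, (self, other), bw)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def pow(self, p: float):
        def bw(g):
            self._accum(g * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), bw)

    # -- activations ------------------------------------------------------
    def sigmoid(self):
        s = expit(self.data)

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def silu(self):
        s = expit(self.data)
        y = self.data * s

        def bw(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(y, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def exp(self):
        y = np.exp(self.data)

        def bw(g):
            self._accum(g * y)

        return Tensor._make(y, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape) / n)

        return Tensor._make(self.data.mean(axis=axis, keepdims=keepdims), (self,), bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        return Tensor._make(y, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# free functions (structural ops)
# ---------------------------------------------------------------------------

def concat(tensors, axis=1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def chunk(t: Tensor, n: int, axis: int = 1):
    size = t.shape[axis] // n
    outs = []
    for i in range(n):
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(i * size, (i + 1) * size)
        outs.append(t[tuple(sl)])
    return outs


def split(t: Tensor, sizes, axis: int = 1):
    offs = np.cumsum([0] + list(sizes))
    outs = []
    for a, b in zip(offs[:-1], offs[1:]):
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(a, b)
        outs.append(t[tuple(sl)])
    return outs


def _pad2d(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution via im2col matmul."""
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    g_ = groups
    assert C == Cg * g_, f"channel mismatch: input {C}, weight expects {Cg * g_}"
    s, p = stride, padding
    xp = _pad2d(x.data, p)
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # (B, C, Ho, Wo, kh, kw)
    cols = win.reshape(B, g_, Cg, Ho, Wo, kh, kw)
    colmat = cols.transpose(0, 1, 3, 4, 2, 5, 6).reshape(B, g_, Ho * Wo, Cg * kh * kw)
    wmat = w.data.reshape(g_, Cout // g_, Cg * kh * kw)
    out = colmat @ wmat.transpose(0, 2, 1)          # (B, g, HoWo, Og)
    out = out.transpose(0, 1, 3, 2).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gmat = g.reshape(B, g_, Cout // g_, Ho * Wo).transpose(0, 1, 3, 2)
        if w.requires_grad:
            dw = np.einsum("bgno,bgnk->gok", gmat, colmat, optimize=True)
            w._accum(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = gmat @ wmat                       # (B, g, HoWo, Cg*kh*kw)
            dcol = dcol.reshape(B, g_, Ho, Wo, Cg, kh, kw).transpose(0, 1, 4, 2, 3, 5, 6)
            dcol = dcol.reshape(B, C, Ho, Wo, kh, kw)
            dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + Ho * s:s, kj:kj + Wo * s:s] += dcol[:, :, :, :, ki, kj]
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return Tensor._make(out, parents, bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.03,
                 eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalization for (B, C, H, W) maps.

    `running_mean`/`running_var` are plain arrays mutated in place during
    training (exponential moving average, torch convention).
    """
    B, C, H, W = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(1, C, 1, 1) * inv.reshape(1, C, 1, 1)
            if training:
                n = B * H * W
                gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gs = gsum.reshape(1, C, 1, 1)
                gxs = gx.reshape(1, C, 1, 1)
                x._accum(gi * (g - gs / n - xhat * gxs / n))
            else:
                x._accum(gi * g)

    return Tensor._make(out, (x, gamma, beta), bw)


def max_pool2d(x: Tensor, k: int, stride: int | None = None, padding: int = 0) -> Tensor:
    s = stride or k
    B, C, H, W = x.shape
    xp = _pad2d(x.data, padding, value=-np.inf)
    Ho = (H + 2 * padding - k) // s + 1
    Wo = (W + 2 * padding - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros((B, C, H + 2 * padding, W + 2 * padding), dtype=np.float32)
        ki, kj = idx // k, idx % k
        bi, ci, ii, jj = np.indices((B, C, Ho, Wo), sparse=False)
        np.add.at(dxp, (bi, ci, ii * s + ki, jj * s + kj), g)
        x._accum(dxp[:, :, padding:padding + H, padding:padding + W] if padding else dxp)

    return Tensor._make(out, (x,), bw)


def avg_pool2d(x: Tensor, k: int, stride: int | None = None) -> Tensor:
    s = stride or k
    B, C, H, W = x.shape
    Ho = (H - k) // s + 1
    Wo = (W - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    out = win.mean(axis=(-1, -2))

    def bw(g):
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        gk = g / (k * k)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki:ki + Ho * s:s, kj:kj + Wo * s:s] += gk
        x._accum(dx)

    return Tensor._make(out, (x,), bw)


def upsample_nearest2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable sigmoid cross-entropy, summed over elements."""
    z, t = logits.data, np.asarray(targets, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weights is not None:
        loss = loss * weights

    def bw(g):
        d = (expit(z) - t)
        if weights is not None:
            d = d * weights
        logits._accum(g * d)

    return Tensor._make(loss.sum(), (logits,), bw)
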
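"""Module system: parameter registration, conv/BN blocks, fusion, SGD.

`ConvBlock` is the standard convolution unit of the detector skeleton
(conv -> batch-norm -> SiLU, bias-free conv).  `fuse()` folds the
batch-norm affine transform into the convolution weights, the form in
which deployed one-stage detectors are shipped and in which model-size
tables report their parameter counts.  Custom attachment modules that
build on raw primitives (the edge-guided attention and the adaptive
downsampler) are not touched by fusion and keep their normalization
explicit.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=trainable)
        self.trainable = trainable


class Module:
    """Lightweight nn.Module analogue with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal --------------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield (prefix + name, val)
        for cname, child in self.named_children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- state ------------------------------------------------------------
    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield (prefix + name, val)
        for cname, child in self.named_children():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict:
        sd = {f"p:{k}": v.data for k, v in self.named_parameters()}
        sd.update({f"b:{k}": v for k, v in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict) -> None:
        params = dict(self.named_parameters())
        for key, arr in sd.items():
            tag, name = key.split(":", 1)
            if tag == "p":
                params[name].data = np.asarray(arr, dtype=np.float32).reshape(params[name].shape)
        # buffers: walk again, assign in place
        bufs = {}
        for k, v in self.named_buffers():
            bufs[k] = v
        for key, arr in sd.items():
            tag, name = key.split(":", 1)
            if tag == "b" and name in bufs:
                bufs[name][...] = arr

    def num_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.data.size for _, p in self.named_parameters()
            if (p.trainable or not trainable_only)
        )


def kaiming_conv(rng: np.random.Generator, cout: int, cin_g: int, k: int) -> np.ndarray:
    fan_in = cin_g * k * k
    bound = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, bound, size=(cout, cin_g, k, k)).astype(np.float32)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training, self.momentum, self.eps)


class ConvBlock(Module):
    """conv(bias-free) + BN + activation; foldable to conv+bias."""

    def __init__(self, rng, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, g: int = 1, act: bool = True):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = (k // 2) if p is None else p
        self.act = act
        self.w = Parameter(kaiming_conv(rng, c2, c1 // g, k))
        self.bn: BatchNorm2d | None = BatchNorm2d(c2)
        self.b: Parameter | None = None  # appears after fusion

    def forward(self, x: Tensor) -> Tensor:
        y = ag.conv2d(x, self.w, self.b, stride=self.s, padding=self.p, groups=self.g)
        if self.bn is not None:
            y = self.bn(y)
        if self.act:
            y = y.silu()
        return y

    def fuse(self) -> None:
        if self.bn is None:
            return
        bn = self.bn
        inv = 1.0 / np.sqrt(bn.running_var + bn.eps)
        scale = bn.gamma.data * inv
        self.w.data = self.w.data * scale.reshape(-1, 1, 1, 1)
        self.b = Parameter(bn.beta.data - bn.gamma.data * bn.running_mean * inv)
        self.bn = None


class PlainConv(Module):
    """Bare conv with bias, no normalization (detection head output convs)."""

    def __init__(self, rng, c1: int, c2: int, k: int = 1, init_bias: float = 0.0):
        super().__init__()
        self.k, self.s, self.p = k, 1, k // 2
        self.w = Parameter(kaiming_conv(rng, c2, c1, k))
        self.b = Parameter(np.full(c2, init_bias, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.s, padding=self.p)


class SGD:
    """SGD with classical momentum."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
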
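"""Structural blocks of the YOLO11-family skeleton.

Replicates the public YOLO11 layer plan — C3k2 bottleneck aggregation,
SPPF spatial pyramid pooling, C2PSA position-sensitive attention and the
decoupled DFL detection head — at configurable width/depth multipliers.
"""

from __future__ import annotations

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import ConvBlock, Module, Parameter, PlainConv


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


class Bottleneck(Module):
    def __init__(self, rng, c1, c2, shortcut=True, k=(3, 3), e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBlock(rng, c1, c_, k[0])
        self.cv2 = ConvBlock(rng, c_, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    """C3 block with 3x3 bottlenecks (used inside C3k2 when c3k=True)."""

    def __init__(self, rng, c1, c2, n=2, shortcut=True, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBlock(rng, c1, c_, 1)
        self.cv2 = ConvBlock(rng, c1, c_, 1)
        self.cv3 = ConvBlock(rng, 2 * c_, c2, 1)
        self.m = [Bottleneck(rng, c_, c_, shortcut, k=(3, 3), e=1.0) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(ag.concat([y, self.cv2(x)], axis=1))


class C3k2(Module):
    """Two-way split/aggregate block (C2f layout with optional C3k inners)."""

    def __init__(self, rng, c1, c2, n=1, c3k=False, e=0.5, shortcut=True):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBlock(rng, c1, 2 * self.c, 1)
        self.cv2 = ConvBlock(rng, (2 + n) * self.c, c2, 1)
        self.m = [
            C3k(rng, self.c, self.c, 2, shortcut) if c3k
            else Bottleneck(rng, self.c, self.c, shortcut, k=(3, 3), e=0.5)
            for _ in range(n)
        ]

    def forward(self, x):
        ys = ag.chunk(self.cv1(x), 2, axis=1)
        for b in self.m:
            ys.append(b(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))


class SPPF(Module):
    def __init__(self, rng, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBlock(rng, c1, c_, 1)
        self.cv2 = ConvBlock(rng, c_ * 4, c2, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ag.max_pool2d(y[-1], self.k, stride=1, padding=self.k // 2))
        return self.cv2(ag.concat(y, axis=1))


class Attention(Module):
    """Multi-head self-attention over flattened spatial positions with a
    depthwise positional-encoding conv (PSA style)."""

    def __init__(self, rng, dim, num_heads, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        h = dim + self.key_dim * num_heads * 2
        self.qkv = ConvBlock(rng, dim, h, 1, act=False)
        self.proj = ConvBlock(rng, dim, dim, 1, act=False)
        self.pe = ConvBlock(rng, dim, dim, 3, g=dim, act=False)

    def forward(self, x):
        B, C, H, W = x.shape
        N = H * W
        qkv = self.qkv(x).reshape(B, self.num_heads, self.key_dim * 2 + self.head_dim, N)
        q, k, v = ag.split(qkv, [self.key_dim, self.key_dim, self.head_dim], axis=2)
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = (v @ attn.transpose(0, 1, 3, 2)).reshape(B, C, H, W)
        out = out + self.pe(v.reshape(B, C, H, W))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, rng, c, num_heads):
        super().__init__()
        self.attn = Attention(rng, c, num_heads)
        self.ffn1 = ConvBlock(rng, c, c * 2, 1)
        self.ffn2 = ConvBlock(rng, c * 2, c, 1, act=False)

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn2(self.ffn1(x))


class C2PSA(Module):
    def __init__(self, rng, c1, c2, n=1, e=0.5):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * e)
        self.cv1 = ConvBlock(rng, c1, 2 * self.c, 1)
        self.cv2 = ConvBlock(rng, 2 * self.c, c1, 1)
        self.m = [PSABlock(rng, self.c, max(self.c // 64, 1)) for _ in range(n)]

    def forward(self, x):
        a, b = ag.chunk(self.cv1(x), 2, axis=1)
        for blk in self.m:
            b = blk(b)
        return self.cv2(ag.concat([a, b], axis=1))


class DetectHead(Module):
    """Decoupled detection head: a box branch regressing per-side distance
    distributions (DFL, reg_max bins) and a depthwise-separable class
    branch, per feature scale.  The DFL projection is a fixed
    (non-trainable) expectation vector."""

    def __init__(self, rng, nc: int, ch: tuple, reg_max: int = 16):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_branches = []
        self.cls_branches = []
        for x in ch:
            self.box_branches.append([
                ConvBlock(rng, x, c2, 3),
                ConvBlock(rng, c2, c2, 3),
                PlainConv(rng, c2, 4 * reg_max, 1, init_bias=1.0),
            ])
            self.cls_branches.append([
                ConvBlock(rng, x, x, 3, g=x),
                ConvBlock(rng, x, c3, 1),
                ConvBlock(rng, c3, c3, 3, g=c3),
                ConvBlock(rng, c3, c3, 1),
                PlainConv(rng, c3, nc, 1, init_bias=-4.6),
            ])
        self.dfl_proj = Parameter(np.arange(reg_max, dtype=np.float32), trainable=False)

    def named_children(self):
        for i, (bb, cb) in enumerate(zip(self.box_branches, self.cls_branches)):
            for j, m in enumerate(bb):
                yield f"box{i}.{j}", m
            for j, m in enumerate(cb):
                yield f"cls{i}.{j}", m

    def forward(self, feats: list) -> list:
        outs = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            y1 = f
            for m in bb:
                y1 = m(y1)
            y2 = f
            for m in cb:
                y2 = m(y2)
            outs.append(ag.concat([y1, y2], axis=1))
        return outs
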
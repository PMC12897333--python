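"""ADown: three-branch information-preserving stride-2 downsampler.

Replaces a full-channel stride-2 3x3 convolution with three parallel
paths whose output channels partition C2 by the floor(C2/3) rule:

    Y1 = SiLU(BN(conv1x1_a(avgpool_2x2,s2(X))))   # Ca channels, stable stats
    Y2 = SiLU(BN(conv3x3,s2_b(X)))                # Cb channels, learnable structure
    Y3 = SiLU(BN(conv1x1_c(maxpool_2x2,s2(X))))   # Cc channels, salient peaks
    Y  = concat(Y1, Y2, Y3)                       # (B, C2, H/2, W/2)

Branch convolutions are bias-free with per-branch batch normalization.
The concatenation order (avg, stride-conv, max) is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import BatchNorm2d, Module, Parameter, kaiming_conv


def adown_channel_split(c2: int) -> tuple[int, int, int]:
    """Partition C2 output channels across the three ADown branches."""
    if c2 < 3:
        raise ValueError(f"ADown needs C2 >= 3 so every branch gets a channel, got {c2}")
    ca = cb = c2 // 3
    return ca, cb, c2 - ca - cb


@dataclass(frozen=True)
class AdownConfig:
    in_channels: int
    out_channels: int
    split: tuple[int, int, int] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "split", adown_channel_split(self.out_channels))


class ADown(Module):
    def __init__(self, rng, cfg: AdownConfig):
        super().__init__()
        self.cfg = cfg
        c1 = cfg.in_channels
        ca, cb, cc = cfg.split
        self.wa = Parameter(kaiming_conv(rng, ca, c1, 1))
        self.bna = BatchNorm2d(ca)
        self.wb = Parameter(kaiming_conv(rng, cb, c1, 3))
        self.bnb = BatchNorm2d(cb)
        self.wc = Parameter(kaiming_conv(rng, cc, c1, 1))
        self.bnc = BatchNorm2d(cc)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.cfg.in_channels:
            raise ValueError(f"ADown expects {self.cfg.in_channels} channels, got {C}")
        if H % 2 or W % 2:
            raise ValueError(f"ADown requires even spatial dims, got {H}x{W}")
        y1 = ag.conv2d(ag.avg_pool2d(x, 2, 2), self.wa)
        y1 = self.bna(y1).silu()
        y2 = ag.conv2d(x, self.wb, stride=2, padding=1)
        y2 = self.bnb(y2).silu()
        y3 = ag.conv2d(ag.max_pool2d(x, 2, 2), self.wc)
        y3 = self.bnc(y3).silu()
        return ag.concat([y1, y2, y3], axis=1)
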
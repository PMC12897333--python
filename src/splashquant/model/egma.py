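"""Edge-guided multi-dimensional attention (EGMA).

The block predicts a single-channel edge-saliency map from the input
features, uses it to form edge-weighted global channel statistics, turns
those into channel-attention weights through a bottlenecked 1x1-conv
MLP, and recalibrates the input as

    E  = sigmoid(BN(conv3x3(X)))        # edge-saliency, (B,1,H,W)
    Xe = X * E                          # edge-weighted features
    G  = spatial_mean(Xe)               # per-channel descriptor
    Ac = sigmoid(MLP(G))                # channel attention, (B,C,1,1)
    Y  = X * Ac * (1 + E)

so channels that respond along splash boundaries are amplified while a
spatial edge-compensation term (1+E) keeps fine boundary cues.  All
convolutions are bias-free; the MLP hidden width is C / mlp_reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import BatchNorm2d, Module, Parameter, kaiming_conv


@dataclass(frozen=True)
class EgmaConfig:
    channels: int
    mlp_reduction: int = 4

    def __post_init__(self):
        if self.mlp_reduction < 1:
            raise ValueError("mlp_reduction must be >= 1")
        if self.channels % self.mlp_reduction != 0:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by "
                f"mlp_reduction ({self.mlp_reduction})"
            )


@dataclass
class EgmaIntermediates:
    """All intermediate maps of one EGMA forward pass (plain arrays)."""
    edge_map: np.ndarray       # E,  (B,1,H,W), strictly in (0,1)
    weighted: np.ndarray       # Xe, (B,C,H,W)
    pooled: np.ndarray         # G,  (B,C,1,1)
    channel_weights: np.ndarray  # Ac, (B,C,1,1), strictly in (0,1)
    output: np.ndarray         # Y,  (B,C,H,W)


class EGMA(Module):
    def __init__(self, rng, cfg: EgmaConfig):
        super().__init__()
        c, r = cfg.channels, cfg.mlp_reduction
        self.cfg = cfg
        self.edge_w = Parameter(kaiming_conv(rng, 1, c, 3))
        self.edge_bn = BatchNorm2d(1)
        self.mlp_w1 = Parameter(kaiming_conv(rng, c // r, c, 1))
        self.mlp_w2 = Parameter(kaiming_conv(rng, c, c // r, 1))

    def forward(self, x: Tensor) -> Tensor:
        return self._run(x)[0]

    def forward_detailed(self, x: Tensor) -> EgmaIntermediates:
        y, inter = self._run(x)
        return inter

    def _run(self, x: Tensor):
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"EGMA configured for {self.cfg.channels} channels, got {x.shape[1]}"
            )
        e = ag.conv2d(x, self.edge_w, padding=1)
        e = self.edge_bn(e).sigmoid()
        xe = x * e
        g = xe.mean(axis=(2, 3), keepdims=True)
        h = ag.conv2d(g, self.mlp_w1).relu()
        ac = ag.conv2d(h, self.mlp_w2).sigmoid()
        y = x * ac * (1.0 + e)
        inter = EgmaIntermediates(
            edge_map=e.data, weighted=xe.data, pooled=g.data,
            channel_weights=ac.data, output=y.data,
        )
        return y, inter
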
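"""Assembly of the splash detector: YOLO11s skeleton + EGMA + ADown + P2.

`build_model` wires the backbone (conv stem, C3k2 stages, SPPF, C2PSA),
the PAN-FPN neck and the decoupled DFL head at strides 4/8/16/32 for the
enabled P2-P5 scales.  EGMA units recalibrate the output of the
configured backbone C3k2 stages; when `use_adown` is set, the stride-2
downsampling convolutions of the bottom-up (PAN) aggregation path are
replaced by the three-branch ADown operator.

Parameter accounting follows the convention of deployed model-size
tables: `count_parameters` reports the network as shipped, i.e. with the
skeleton's conv+BN blocks folded (`fuse=True`, the default) and the
fixed DFL projection included, while attachment modules (EGMA, ADown)
keep their normalization explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.modules import ConvBlock, Module
from .adown import ADown, AdownConfig
from .blocks import C2PSA, C3k2, DetectHead, SPPF, make_divisible
from .egma import EGMA, EgmaConfig

ALL_SCALES = ("P2", "P3", "P4", "P5")
STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}
VALID_EGMA_LAYERS = (2, 4, 6, 8)


@dataclass
class ModelConfig:
    num_classes: int = 1
    input_size: tuple = (640, 640)
    scales: tuple = ("P3", "P4", "P5")
    egma_layers: tuple = ()
    mlp_reduction: int = 4
    use_adown: bool = False
    width_multiple: float = 0.50   # YOLO11s scale
    depth_multiple: float = 0.50
    max_channels: int = 1024
    reg_max: int = 16
    seed: int = 0

    def __post_init__(self):
        self.scales = tuple(s for s in ALL_SCALES if s in tuple(self.scales))
        if self.scales not in (("P3", "P4", "P5"), ("P2", "P3", "P4", "P5")):
            raise ValueError(f"unsupported scale set {self.scales}; "
                             "use P3-P5 or P2-P5")
        bad = [i for i in self.egma_layers if i not in VALID_EGMA_LAYERS]
        if bad:
            raise ValueError(f"egma_layers {bad} not in valid C3k2 stages "
                             f"{VALID_EGMA_LAYERS}")
        div = 64 if "P2" in self.scales else 32
        h, w = self.input_size
        if h % div or w % div:
            raise ValueError(f"input_size {self.input_size} must be divisible by {div}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["scales"] = list(self.scales)
        d["egma_layers"] = list(self.egma_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("input_size", "scales", "egma_layers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ParamReport:
    blocks: dict
    total: int
    trainable: int

    def to_json(self) -> str:
        return json.dumps({"blocks": self.blocks, "total": self.total,
                           "trainable": self.trainable}, indent=2)

    def to_text(self) -> str:
        width = max(len(k) for k in self.blocks) if self.blocks else 10
        lines = [f"{k:<{width}}  {v:>12,}" for k, v in self.blocks.items()]
        lines.append(f"{'total':<{width}}  {self.total:>12,}")
        return "\n".join(lines)


class _Stage(Module):
    """A named sequence of modules (for per-block reporting)."""

    def __init__(self, mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class _EgmaC3k2(Module):
    """C3k2 stage with post-block EGMA recalibration."""

    def __init__(self, block: C3k2, egma: EGMA):
        super().__init__()
        self.block = block
        self.egma = egma

    def forward(self, x):
        return self.egma(self.block(x))


class SplashDetector(Module):
    """The assembled network.  forward() maps (B,3,H,W) arrays/tensors to a
    dict of per-scale raw prediction maps (B, 4*reg_max + nc, H/s, W/s)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)

        def ch(c):
            return make_divisible(min(c, cfg.max_channels) * cfg.width_multiple, 8)

        def d(n):
            return max(round(n * cfg.depth_multiple), 1)

        c64, c128, c256 = ch(64), ch(128), ch(256)
        c512, c1024 = ch(512), ch(1024)
        self._chs = (c128, c256, c512, c1024)
        n = d(2)

        def c3k2_stage(layer_idx, c1, c2, c3k, e=0.5):
            blk = C3k2(rng, c1, c2, n, c3k, e)
            if layer_idx in cfg.egma_layers:
                return _EgmaC3k2(blk, EGMA(rng, EgmaConfig(c2, cfg.mlp_reduction)))
            return blk

        # backbone (stage numbering follows the layer plan)
        self.stem0 = ConvBlock(rng, 3, c64, 3, 2)
        self.stem1 = ConvBlock(rng, c64, c128, 3, 2)
        self.stage2 = c3k2_stage(2, c128, c256, False, 0.25)
        self.down3 = ConvBlock(rng, c256, c256, 3, 2)
        self.stage4 = c3k2_stage(4, c256, c512, False, 0.25)
        self.down5 = ConvBlock(rng, c512, c512, 3, 2)
        self.stage6 = c3k2_stage(6, c512, c512, True)
        self.down7 = ConvBlock(rng, c512, c1024, 3, 2)
        self.stage8 = c3k2_stage(8, c1024, c1024, True)
        self.sppf = SPPF(rng, c1024, c1024)
        self.psa = C2PSA(rng, c1024, c1024, n)

        # top-down FPN
        self.fpn_p4 = C3k2(rng, c1024 + c512, c512, n, False)
        self.fpn_p3 = C3k2(rng, c512 + c512, c256, n, False)
        self.with_p2 = "P2" in cfg.scales
        if self.with_p2:
            self.fpn_p2 = C3k2(rng, c256 + c256, c128, n, False)

        def downsamp(c):
            if cfg.use_adown:
                return ADown(rng, AdownConfig(c, c))
            return ConvBlock(rng, c, c, 3, 2)

        # bottom-up PAN
        if self.with_p2:
            self.pan_d2 = downsamp(c128)
            self.pan_p3 = C3k2(rng, c128 + c256, c256, n, False)
        self.pan_d3 = downsamp(c256)
        self.pan_p4 = C3k2(rng, c256 + c512, c512, n, False)
        self.pan_d4 = downsamp(c512)
        self.pan_p5 = C3k2(rng, c512 + c1024, c1024, n, True)

        head_ch = ((c128, c256, c512, c1024) if self.with_p2
                   else (c256, c512, c1024))
        self.head = DetectHead(rng, cfg.num_classes, head_ch, cfg.reg_max)

    # -- forward ----------------------------------------------------------
    def forward(self, x) -> dict:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W) input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        div = 64 if self.with_p2 else 32
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by {div}")

        x = self.stem1(self.stem0(x))
        p2 = self.stage2(x)
        p3 = self.stage4(self.down3(p2))
        p4 = self.stage6(self.down5(p3))
        p5 = self.psa(self.sppf(self.stage8(self.down7(p4))))

        f4 = self.fpn_p4(ag.concat([ag.upsample_nearest2(p5), p4], axis=1))
        f3 = self.fpn_p3(ag.concat([ag.upsample_nearest2(f4), p3], axis=1))
        if self.with_p2:
            f2 = self.fpn_p2(ag.concat([ag.upsample_nearest2(f3), p2], axis=1))
            o3 = self.pan_p3(ag.concat([self.pan_d2(f2), f3], axis=1))
        else:
            o3 = f3
        o4 = self.pan_p4(ag.concat([self.pan_d3(o3), f4], axis=1))
        o5 = self.pan_p5(ag.concat([self.pan_d4(o4), p5], axis=1))

        feats = ([f2, o3, o4, o5] if self.with_p2 else [o3, o4, o5])
        outs = self.head(feats)
        return dict(zip(self.cfg.scales, outs))

    @property
    def strides(self) -> dict:
        return {s: STRIDES[s] for s in self.cfg.scales}

    # -- fusion -----------------------------------------------------------
    def fuse(self) -> "SplashDetector":
        """Fold batch-norm into the skeleton's conv blocks (deploy form)."""
        for m in self.modules():
            if isinstance(m, ConvBlock):
                m.fuse()
        self.eval()
        return self

    def block_names(self):
        yield from self.named_children()


def build_model(cfg: ModelConfig) -> SplashDetector:
    return SplashDetector(cfg)


def count_parameters(net: SplashDetector | Module, fused: bool | None = None) -> ParamReport:
    """Per-block and total parameter counts.

    fused=True (default for an unfused SplashDetector) reports the
    deploy-form count: a copy of the network is BN-folded first.  The
    fixed DFL projection is included in `total` but not in `trainable`.
    """
    if fused and isinstance(net, SplashDetector):
        copy = build_model(net.cfg)
        copy.load_state_dict(net.state_dict())
        copy.fuse()
        net = copy
    elif fused is None and isinstance(net, SplashDetector):
        return count_parameters(net, fused=True)
    blocks = {}
    for name, child in net.named_children():
        blocks[name] = child.num_parameters()
    own = {k: v for k, v in vars(net).items() if hasattr(v, "trainable")}
    for k, v in own.items():
        blocks[k] = v.data.size
    total = net.num_parameters()
    trainable = net.num_parameters(trainable_only=True)
    assert total == sum(blocks.values())
    return ParamReport(blocks=blocks, total=total, trainable=trainable)
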
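"""Assembly of the segmentation network.

The improved configuration wires: MobileOne-S0 encoder (natural output
stride 16, 256-channel high tap) -> ASPP with strip-pooling context branch
and SimAM at position B -> 3x3 context-refinement conv -> x4 bilinear
upsampling -> CGA mixup fusion with the projected stride-4 low-level
features -> 3x3 decoder conv -> 1x1 classifier -> bilinear upsampling to
the input resolution.  Ablation toggles recover the stock DeepLabv3+ head
(image pooling, concatenation decoder with two 3x3 convs) and the
MobileNetV2 reference used for complexity calibration.

SimAM positions (all parameter-free):
  A - on the low-level features, before their 1x1 reduction;
  B - after the ASPP branch concatenation, before the 1x1 projection;
  C - after feature fusion, before the 3x3 decoder conv.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .backbone import build_mobileone_s0
from .context import ASPP, ASPPConfig, SimAM
from .fusion import CGAConfig, CGAFusion
from .mobilenetv2 import MobileNetV2Backbone
from .nn import Tensor, concat
from .nn import functional as F


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 5
    input_size: tuple = (512, 512)
    backbone: str = "mobileone_s0"          # or "mobilenetv2"
    backbone_mode: str = "train"            # or "merged"
    output_stride: int | None = None        # default: 16 (S0) / 8 (MobileNetV2)
    simam_positions: frozenset = frozenset({"B"})
    use_strip_pool: bool = True
    fusion_mode: str = "cga_mixup"          # or "concat"
    aspp_rates: tuple = (6, 12, 18)
    aspp_channels: int = 256
    simam_lambda: float = 1e-4
    reduction_ratio: int = 8
    shuffle_groups: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.fusion_mode not in ("concat", "cga_mixup"):
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        if self.backbone not in ("mobileone_s0", "mobilenetv2"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone_mode not in ("train", "merged"):
            raise ValueError(f"unknown backbone mode {self.backbone_mode!r}")
        bad = set(self.simam_positions) - {"A", "B", "C"}
        if bad:
            raise ValueError(f"unknown SimAM positions {sorted(bad)}")
        object.__setattr__(self, "simam_positions", frozenset(self.simam_positions))

    @property
    def resolved_output_stride(self) -> int:
        if self.output_stride is not None:
            return self.output_stride
        return 8 if self.backbone == "mobilenetv2" else 16


def baseline_config(backbone: str = "mobilenetv2", **kw) -> ModelConfig:
    """Stock DeepLabv3+ head (Tables 2-3 reference rows)."""
    return ModelConfig(backbone=backbone, simam_positions=frozenset(),
                       use_strip_pool=False, fusion_mode="concat", **kw)


class SegmentationModel(nn.Module):
    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        d = cfg.aspp_channels
        os_ = cfg.resolved_output_stride
        if cfg.backbone == "mobileone_s0":
            self.backbone = build_mobileone_s0(
                output_stride=os_ if os_ in (16, 32) else 16,
                mode=cfg.backbone_mode, rng=rng)
        else:
            self.backbone = MobileNetV2Backbone(output_stride=os_, rng=rng)
        self.aspp = ASPP(self.backbone.out_channels,
                         ASPPConfig(cfg.aspp_rates, d, cfg.use_strip_pool,
                                    "B" in cfg.simam_positions, cfg.simam_lambda),
                         rng=rng)
        self.simam_a = SimAM(cfg.simam_lambda) if "A" in cfg.simam_positions else None
        self.simam_c = SimAM(cfg.simam_lambda) if "C" in cfg.simam_positions else None
        self.low_reduce = nn.ConvBNReLU(self.backbone.low_channels, 48, 1, rng=rng)
        if cfg.fusion_mode == "cga_mixup":
            self.refine = nn.ConvBNReLU(d, d, 3, padding=1, rng=rng)
            self.low_proj = nn.ConvBNReLU(48, d, 1, rng=rng)
            self.fusion = CGAFusion(d, CGAConfig(cfg.reduction_ratio,
                                                 shuffle_groups=cfg.shuffle_groups),
                                    rng=rng)
            self.decoder = nn.ConvBNReLU(d, d, 3, padding=1, rng=rng)
        else:
            self.decoder = nn.Sequential(
                nn.ConvBNReLU(48 + d, d, 3, padding=1, rng=rng),
                nn.ConvBNReLU(d, d, 3, padding=1, rng=rng))
        self.classifier = nn.Conv2d(d, cfg.num_classes, 1, bias=True, rng=rng)

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        low, high = self.backbone(x)
        y = self.aspp(high)
        if self.simam_a is not None:
            low = self.simam_a(low)
        low = self.low_reduce(low)
        lh, lw = low.shape[2:]
        if self.cfg.fusion_mode == "cga_mixup":
            y = self.refine(y)
            y = F.interpolate_bilinear(y, lh, lw)
            fused = self.fusion(self.low_proj(low), y)
            if self.simam_c is not None:
                fused = self.simam_c(fused)
            y = self.decoder(fused)
        else:
            y = F.interpolate_bilinear(y, lh, lw)
            y = concat([y, low], axis=1)
            if self.simam_c is not None:
                y = self.simam_c(y)
            y = self.decoder(y)
        logits = self.classifier(y)
        return F.interpolate_bilinear(logits, h, w)

    def fuse(self) -> "SegmentationModel":
        """Model copy with a structurally reparameterized (merged) backbone."""
        m = SegmentationModel.__new__(SegmentationModel)
        nn.Module.__init__(m)
        m.cfg = replace(self.cfg, backbone_mode="merged")
        m.backbone = self.backbone.fuse()
        for name in ("aspp", "simam_a", "simam_c", "low_reduce", "refine",
                     "low_proj", "fusion", "decoder", "classifier"):
            if hasattr(self, name):
                setattr(m, name, getattr(self, name))
        m.eval()
        return m


def build_model(cfg: ModelConfig, rng=None) -> SegmentationModel:
    return SegmentationModel(cfg, rng=rng)


def predict(model: SegmentationModel, images: np.ndarray) -> np.ndarray:
    """Label maps (argmax over the class axis) for a batch of images."""
    model.eval()
    with nn.no_grad():
        logits = model(Tensor(np.asarray(images, dtype=np.float32)))
    return np.argmax(logits.data, axis=1).astype(np.int64)
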
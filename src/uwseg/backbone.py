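"""MobileOne backbone with structural reparameterization.

Each stage is a stack of MobileOne blocks: a depthwise 3x3 unit followed by a
pointwise 1x1 unit.  During training every unit carries ``k`` parallel
conv+BN branches, a 1x1 conv+BN scale branch (3x3 units only) and a BN-only
identity branch (when shapes permit); at inference all branches fold
algebraically into one convolution with bias.  The S0 configuration
(width multiplier alpha, over-parameterization factor k per stage) is the
variant used for segmentation here; the other variants' specifications are
stored for reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F


@dataclass(frozen=True)
class StageSpec:
    """One convolutional stage of the MobileOne trunk."""
    stage_index: int
    input_resolution: int
    blocks: int
    stride: int
    base_channels: int
    alpha: float
    k: int
    activation: str = "relu"

    def __post_init__(self):
        if self.blocks < 1 or self.k < 1:
            raise ValueError("blocks and k must be >= 1")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.channels <= 0:
            raise ValueError("channels must be positive")
        if self.activation not in ("relu", "se_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def channels(self) -> int:
        return round(self.base_channels * self.alpha)


def mobileone_stage_specs(variant: str = "s0") -> list[StageSpec]:
    """Convolutional stages 1-6 of a MobileOne variant (classifier head omitted)."""
    base = [  # (input_res, blocks, stride, base_channels)
        (224, 1, 2, 64), (112, 2, 2, 64), (56, 8, 2, 128),
        (28, 5, 2, 256), (14, 5, 1, 256), (14, 1, 2, 512),
    ]
    alpha_k = {
        "s0": [(0.75, 4), (0.75, 4), (1.0, 4), (1.0, 4), (1.0, 4), (2.0, 4)],
        "s1": [(1.5, 1), (1.5, 1), (1.5, 1), (2.0, 1), (2.0, 1), (2.5, 1)],
        "s2": [(1.5, 1), (1.5, 1), (2.0, 1), (2.5, 1), (2.5, 1), (4.0, 1)],
        "s3": [(2.0, 1), (2.0, 1), (2.5, 1), (3.0, 1), (3.0, 1), (4.0, 1)],
        "s4": [(3.0, 1), (3.0, 1), (3.5, 1), (3.5, 1), (3.5, 1), (4.0, 1)],
    }[variant.lower()]
    act = ["relu"] * 6
    if variant.lower() == "s4":
        act[4] = act[5] = "se_relu"
    return [StageSpec(i + 1, r, b, s, c, a, k, ac)
            for i, ((r, b, s, c), (a, k), ac) in enumerate(zip(base, alpha_k, act))]


S0_STAGE_CHANNELS = (48, 48, 128, 256, 256, 1024)


class FeaturePair(NamedTuple):
    low: Tensor    # stride-4 tap
    high: Tensor   # encoder output tap


class MergedKernel(NamedTuple):
    weight: np.ndarray  # (out_ch, in_ch/groups, 3, 3) -- or 1x1 for pointwise units
    bias: np.ndarray


# ---------------------------------------------------------------------------
# reparameterization algebra
# ---------------------------------------------------------------------------

def fuse_conv_bn(weight: np.ndarray, bn) -> MergedKernel:
    """Fold an inference-mode BN into the preceding conv.

    ``bn`` is either a BatchNorm2d module or a tuple (gamma, beta, mean, var, eps).
    W' = W * gamma / sqrt(var + eps);  b' = beta - gamma * mean / sqrt(var + eps).
    """
    if isinstance(bn, nn.BatchNorm2d):
        gamma, beta = bn.weight.data, bn.bias.data
        mean, var, eps = bn.running_mean, bn.running_var, bn.eps
    else:
        gamma, beta, mean, var, eps = bn
        gamma, beta = np.asarray(gamma, np.float32), np.asarray(beta, np.float32)
        mean, var = np.asarray(mean, np.float32), np.asarray(var, np.float32)
    weight = np.asarray(weight, np.float32)
    if not (weight.shape[0] == gamma.size == beta.size == mean.size == var.size):
        raise ValueError(
            f"fuse_conv_bn: conv has {weight.shape[0]} output channels but BN has "
            f"{gamma.size} statistics")
    if np.any(var < 0):
        raise ValueError("fuse_conv_bn: negative variance")
    scale = gamma / np.sqrt(var + eps)
    return MergedKernel(weight * scale.reshape(-1, 1, 1, 1), beta - mean * scale)


def pad_1x1_to_3x3(weight: np.ndarray) -> np.ndarray:
    """Embed a 1x1 kernel at the center tap of a zero 3x3 kernel."""
    weight = np.asarray(weight, np.float32)
    if weight.shape[-2:] != (1, 1):
        raise ValueError(f"expected 1x1 kernel, got {weight.shape}")
    return np.pad(weight, ((0, 0), (0, 0), (1, 1), (1, 1)))


def identity_to_kernel(channels: int, groups: int, kernel_size: int = 3) -> np.ndarray:
    """3x3 kernel implementing the identity map under the given grouping."""
    if channels % groups:
        raise ValueError(f"channels {channels} not divisible by groups {groups}")
    in_g = channels // groups
    w = np.zeros((channels, in_g, kernel_size, kernel_size), dtype=np.float32)
    c = kernel_size // 2
    for o in range(channels):
        w[o, o % in_g, c, c] = 1.0
    return w


# ---------------------------------------------------------------------------
# reparameterizable unit and block
# ---------------------------------------------------------------------------

class MobileOneUnit(nn.Module):
    """One reparameterizable conv unit (conv branches + scale + identity -> ReLU)."""

    def __init__(self, in_ch, out_ch, kernel_size, stride=1, groups=1,
                 num_branches=1, dilation=1, merged=False, rng=None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel_size
        self.stride, self.groups, self.dilation = stride, groups, dilation
        self.num_branches = num_branches
        self.padding = dilation * (kernel_size // 2)
        self.merged = merged
        if merged:
            self.reparam = nn.Conv2d(in_ch, out_ch, kernel_size, stride,
                                     self.padding, dilation, groups, bias=True, rng=rng)
        else:
            self.conv_branches = [
                nn.ConvBN(in_ch, out_ch, kernel_size, stride, self.padding,
                          dilation, groups, rng=rng)
                for _ in range(num_branches)]
            self.scale = (nn.ConvBN(in_ch, out_ch, 1, stride, 0, 1, groups, rng=rng)
                          if kernel_size > 1 else None)
            self.skip = (nn.BatchNorm2d(in_ch)
                         if in_ch == out_ch and stride == 1 else None)

    def forward(self, x):
        if self.merged:
            return self.reparam(x).relu()
        out = self.conv_branches[0](x)
        for br in self.conv_branches[1:]:
            out = out + br(x)
        if self.scale is not None:
            out = out + self.scale(x)
        if self.skip is not None:
            out = out + self.skip(x)
        return out.relu()

    def merge_kernel(self) -> MergedKernel:
        """Collapse all branches into a single (weight, bias)."""
        if self.merged:
            return MergedKernel(self.reparam.weight.data.copy(),
                                self.reparam.bias.data.copy())
        w = np.zeros((self.out_ch, self.in_ch // self.groups, self.k, self.k),
                     dtype=np.float32)
        b = np.zeros(self.out_ch, dtype=np.float32)
        for br in self.conv_branches:
            bw, bb = fuse_conv_bn(br.conv.weight.data, br.bn)
            w += bw
            b += bb
        if self.scale is not None:
            sw, sb = fuse_conv_bn(self.scale.conv.weight.data, self.scale.bn)
            w += pad_1x1_to_3x3(sw) if self.k == 3 else sw
            b += sb
        if self.skip is not None:
            iw = identity_to_kernel(self.in_ch, self.groups, self.k)
            sw, sb = fuse_conv_bn(iw, self.skip)
            w += sw
            b += sb
        return MergedKernel(w, b)

    def fuse(self) -> "MobileOneUnit":
        """Return the single-conv inference-equivalent unit."""
        kern = self.merge_kernel()
        m = MobileOneUnit(self.in_ch, self.out_ch, self.k, self.stride,
                          self.groups, dilation=self.dilation, merged=True)
        m.reparam.weight.data[...] = kern.weight
        m.reparam.bias.data[...] = kern.bias
        return m


def reparameterize_block(unit: MobileOneUnit) -> MergedKernel:
    """Spec-level alias: merge one multi-branch unit into a single kernel."""
    return unit.merge_kernel()


class MobileOneBlock(nn.Module):
    """Depthwise 3x3 unit followed by pointwise 1x1 unit."""

    def __init__(self, in_ch, out_ch, stride, k, dilation=1, merged=False, rng=None):
        super().__init__()
        self.dw = MobileOneUnit(in_ch, in_ch, 3, stride, groups=in_ch,
                                num_branches=k, dilation=dilation, merged=merged, rng=rng)
        self.pw = MobileOneUnit(in_ch, out_ch, 1, 1, groups=1,
                                num_branches=k, merged=merged, rng=rng)

    def forward(self, x):
        return self.pw(self.dw(x))

    def fuse(self):
        b = MobileOneBlock.__new__(MobileOneBlock)
        nn.Module.__init__(b)
        b.dw = self.dw.fuse()
        b.pw = self.pw.fuse()
        return b


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class MobileOneBackbone(nn.Module):
    """Stem + stages with named feature taps.

    ``num_stages`` counts the Table-style stages (1 = stem only).  The
    segmentation models use ``num_stages=5`` (high tap at 256 channels,
    natural output stride 16); ``num_stages=6`` appends the wide expansion
    stage (1024 channels) at output stride 32, or dilated at 16.
    """

    def __init__(self, specs: list[StageSpec] | None = None, num_stages: int = 5,
                 output_stride: int = 16, mode: str = "train", rng=None):
        super().__init__()
        specs = specs or mobileone_stage_specs("s0")
        validate_stage_specs(specs)
        if num_stages < 2 or num_stages > len(specs):
            raise ValueError(f"num_stages must be in [2, {len(specs)}]")
        if output_stride not in (16, 32):
            raise ValueError("output_stride must be 16 or 32")
        merged = {"train": False, "inference": True, "merged": True}[mode]
        self.specs = specs[:num_stages]
        self.mode = "merged" if merged else "train"
        self.output_stride = output_stride

        stem_spec = specs[0]
        ch = stem_spec.channels
        # stem: single 3x3 unit, stride 2
        self.stem = MobileOneUnit(3, ch, 3, 2, num_branches=1, merged=merged, rng=rng)
        stages = []
        stride_prod = 2
        self.low_index = None
        for spec in specs[1:num_stages]:
            blocks = []
            for bi in range(spec.blocks):
                s = spec.stride if bi == 0 else 1
                dil = 1
                if s == 2:
                    if stride_prod * 2 > output_stride:
                        s, dil = 1, 2     # dilate instead of striding
                    else:
                        stride_prod *= 2
                blocks.append(MobileOneBlock(ch, spec.channels, s, spec.k,
                                             dilation=dil, merged=merged, rng=rng))
                ch = spec.channels
            stages.append(nn.Sequential(*blocks))
            if stride_prod == 4 and self.low_index is None:
                self.low_index = len(stages) - 1
        self.stages = stages
        self.out_channels = ch
        self.low_channels = specs[self.low_index + 1].channels

    def forward(self, x) -> FeaturePair:
        x = self.stem(x)
        low = None
        for i, st in enumerate(self.stages):
            x = st(x)
            if i == self.low_index:
                low = x
        return FeaturePair(low, x)

    def fuse(self) -> "MobileOneBackbone":
        """Structurally reparameterized copy (every unit a single conv)."""
        fb = MobileOneBackbone.__new__(MobileOneBackbone)
        nn.Module.__init__(fb)
        fb.specs, fb.mode = self.specs, "merged"
        fb.output_stride = self.output_stride
        fb.low_index = self.low_index
        fb.out_channels, fb.low_channels = self.out_channels, self.low_channels
        fb.stem = self.stem.fuse()
        fb.stages = [nn.Sequential(*[b.fuse() for b in st]) for st in self.stages]
        return fb


def validate_stage_specs(specs: list[StageSpec]):
    if [s.blocks for s in specs] != [1, 2, 8, 5, 5, 1][:len(specs)]:
        raise ValueError("stage block counts must follow the MobileOne layout")
    if [s.stride for s in specs] != [2, 2, 2, 2, 1, 2][:len(specs)]:
        raise ValueError("stage strides must follow the MobileOne layout")


def build_mobileone_s0(num_stages: int = 5, output_stride: int = 16,
                       mode: str = "train", rng=None) -> MobileOneBackbone:
    """MobileOne-S0 trunk for segmentation (classifier stages omitted)."""
    return MobileOneBackbone(mobileone_stage_specs("s0"), num_stages,
                             output_stride, mode, rng=rng)


def extract_features(backbone: MobileOneBackbone, image: Tensor) -> FeaturePair:
    """Run the trunk; image spatial size must be divisible by 32."""
    if isinstance(image, np.ndarray):
        image = Tensor(image)
    h, w = image.shape[-2:]
    if h % 32 or w % 32:
        raise ValueError(f"input size {h}x{w} not divisible by 32")
    return backbone(image)
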
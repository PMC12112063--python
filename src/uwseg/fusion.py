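"""Content-guided attention (CGA) and the mixup fusion of decoder features.

CGA produces a channel-specific spatial importance map W in (0,1)^CxHxW from
parallel channel attention and spatial attention, refined by the feature
content through channel shuffling and a channel-grouped 7x7 convolution.
The decoder then blends detail (low-level) and semantic (high-level) streams
convexly: conv(low * W + high * (1 - W)), replacing concatenation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat
from .nn import functional as F


@dataclass(frozen=True)
class CGAConfig:
    reduction_ratio: int = 8
    spatial_kernel: int = 7
    group_kernel: int = 7
    shuffle_groups: int = 2

    def __post_init__(self):
        if self.spatial_kernel % 2 == 0 or self.group_kernel % 2 == 0:
            raise ValueError("attention kernels must be odd")
        if self.reduction_ratio < 1 or self.shuffle_groups < 1:
            raise ValueError("ratios must be >= 1")


class ChannelAttention(nn.Module):
    """GAP -> 1x1 (C -> C/r) -> ReLU -> 1x1 (C/r -> C); no squashing here."""

    def __init__(self, channels: int, reduction_ratio: int = 8, rng=None):
        super().__init__()
        if channels < reduction_ratio or channels % reduction_ratio:
            raise ValueError(
                f"channels {channels} must be divisible by reduction ratio {reduction_ratio}")
        mid = channels // reduction_ratio
        self.fc1 = nn.Conv2d(channels, mid, 1, bias=True, rng=rng)
        self.fc2 = nn.Conv2d(mid, channels, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.fc2(self.fc1(F.global_avg_pool(x)).relu())


class SpatialAttention(nn.Module):
    """[channel-mean map, channel-max map] -> 7x7 conv -> 1xHxW."""

    def __init__(self, kernel: int = 7, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, bias=True, rng=rng)

    def forward(self, x):
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = x.max(axis=1, keepdims=True)
        return self.conv(concat([mean_map, max_map], axis=1))


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    return F.channel_shuffle(x, groups)


class CGA(nn.Module):
    """Two-stage spatial-importance-map generator (Eqs-style pipeline)."""

    def __init__(self, channels: int, cfg: CGAConfig = CGAConfig(), rng=None):
        super().__init__()
        self.cfg = cfg
        self.channels = channels
        self.channel_attn = ChannelAttention(channels, cfg.reduction_ratio, rng=rng)
        self.spatial_attn = SpatialAttention(cfg.spatial_kernel, rng=rng)
        # grouped refinement: 2C -> C with one group per output channel, so each
        # channel's importance map sees its own (content, coarse-SIM) pair
        self.group_conv = nn.Conv2d(2 * channels, channels, cfg.group_kernel,
                                    padding=cfg.group_kernel // 2,
                                    groups=channels, bias=True, rng=rng)

    def forward(self, x) -> Tensor:
        wc = self.channel_attn(x)                  # (n, c, 1, 1)
        ws = self.spatial_attn(x)                  # (n, 1, h, w)
        w_cos = wc + ws                            # broadcast to (n, c, h, w)
        mixed = channel_shuffle(concat([x, w_cos], axis=1), self.cfg.shuffle_groups)
        return self.group_conv(mixed).sigmoid()


def compute_sim(x: Tensor, cfg: CGAConfig = CGAConfig(), module: CGA | None = None,
                rng=None) -> Tensor:
    """Spatial importance map of ``x``; builds a fresh CGA if none is given."""
    if isinstance(x, np.ndarray):
        x = Tensor(x)
    cga = module if module is not None else CGA(x.shape[1], cfg, rng=rng)
    return cga(x)


class CGAFusion(nn.Module):
    """Mixup fusion: out = conv(low * W + high * (1-W)), W = CGA(low + high)."""

    def __init__(self, channels: int, cfg: CGAConfig = CGAConfig(), rng=None):
        super().__init__()
        self.cga = CGA(channels, cfg, rng=rng)
        self.out_conv = nn.Conv2d(channels, channels, 1, bias=True, rng=rng)
        self.out_bn = nn.BatchNorm2d(channels)

    def forward(self, low, high, weight_override: Tensor | None = None):
        if low.shape != high.shape:
            raise ValueError(f"fusion streams differ: {low.shape} vs {high.shape}")
        w = weight_override if weight_override is not None else self.cga(low + high)
        mixed = low * w + high * (1.0 - w)
        return self.out_bn(self.out_conv(mixed))


def mixup_fuse(low: Tensor, high: Tensor, cfg: CGAConfig = CGAConfig(),
               module: CGAFusion | None = None, rng=None) -> Tensor:
    if isinstance(low, np.ndarray):
        low = Tensor(low)
    if isinstance(high, np.ndarray):
        high = Tensor(high)
    fuser = module if module is not None else CGAFusion(low.shape[1], cfg, rng=rng)
    return fuser(low, high)
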
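"""Context aggregation head: SimAM attention, strip pooling, and ASPP.

The ASPP keeps the classic five-branch layout (1x1, three atrous 3x3, one
global-context branch).  The global-context branch is either the stock
image-pooling branch or, in the improved configuration, a strip-pooling
gate that rescales the feature map with sigmoid-activated row/column mean
profiles.  SimAM can be inserted after the branch concatenation, before the
1x1 projection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat
from .nn import functional as F


@dataclass(frozen=True)
class SimAMConfig:
    lambda_reg: float = 1e-4

    def __post_init__(self):
        if self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be positive")


def simam_attention(x: Tensor, cfg: SimAMConfig | float = SimAMConfig()) -> Tensor:
    """Parameter-free energy-based attention.

    Per channel, with spatial mean u and variance s2 = sum((x-u)^2)/(M-1),
    the inverse energy of each neuron is (x-u)^2 / (4*(s2+lambda)) + 0.5 and
    the feature map is rescaled by its sigmoid.  Outliers relative to their
    channel receive weights above sigmoid(0.5); a flat channel receives the
    neutral weight sigmoid(0.5) everywhere (also the single-pixel fallback).
    """
    lam = cfg.lambda_reg if isinstance(cfg, SimAMConfig) else float(cfg)
    if isinstance(x, np.ndarray):
        x = Tensor(x)
    n, c, h, w = x.shape
    m = h * w
    if m < 2:
        return x * float(1.0 / (1.0 + np.exp(-0.5)))
    mu = x.mean(axis=(2, 3), keepdims=True)
    d = x - mu
    d2 = d * d
    s2 = d2.sum(axis=(2, 3), keepdims=True) * (1.0 / (m - 1))
    e_inv = d2 / ((s2 + lam) * 4.0) + 0.5
    return x * e_inv.sigmoid()


class SimAM(nn.Module):
    """Module wrapper; carries zero learnable parameters by construction."""

    def __init__(self, lambda_reg: float = 1e-4):
        super().__init__()
        self.cfg = SimAMConfig(lambda_reg)

    def forward(self, x):
        return simam_attention(x, self.cfg)


def strip_profiles(x: Tensor | np.ndarray):
    """Row/column mean profiles and their broadcast sum.

    Returns (yh, yv, y) with yh[..., i] the mean of row i, yv[..., j] the mean
    of column j, and y[..., i, j] = yh[..., i] + yv[..., j].
    """
    if isinstance(x, np.ndarray):
        x = Tensor(x)
    yh = x.mean(axis=3, keepdims=True)   # (n, c, h, 1)
    yv = x.mean(axis=2, keepdims=True)   # (n, c, 1, w)
    y = yh + yv
    return yh, yv, y


class StripPooling(nn.Module):
    """z = X * sigmoid(f(y)) with f a 1x1 conv over the mixed profile map."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.f = nn.Conv2d(channels, channels, 1, bias=True, rng=rng)

    def forward(self, x):
        _, _, y = strip_profiles(x)
        return x * self.f(y).sigmoid()


def strip_pool(x: Tensor, f: nn.Conv2d) -> Tensor:
    """Functional form of the strip-pooling gate with a caller-supplied f."""
    _, _, y = strip_profiles(x)
    return x * f(y).sigmoid()


@dataclass(frozen=True)
class ASPPConfig:
    atrous_rates: tuple = (6, 12, 18)
    branch_channels: int = 256
    use_strip_pool: bool = True
    use_simam: bool = True
    simam_lambda: float = 1e-4

    def __post_init__(self):
        r = self.atrous_rates
        if any(a <= 0 for a in r) or list(r) != sorted(set(r)):
            raise ValueError("atrous rates must be positive and strictly increasing")


class ASPP(nn.Module):
    """Five-branch atrous spatial pyramid pooling with configurable context branch."""

    def __init__(self, in_ch: int, cfg: ASPPConfig = ASPPConfig(), rng=None):
        super().__init__()
        self.cfg = cfg
        d = cfg.branch_channels
        self.branch1 = nn.ConvBNReLU(in_ch, d, 1, rng=rng)
        self.atrous = [nn.ConvBNReLU(in_ch, d, 3, padding=r, dilation=r, rng=rng)
                       for r in cfg.atrous_rates]
        if cfg.use_strip_pool:
            self.context = StripPooling(in_ch, rng=rng)
            # strip gate preserves channel count; project only if it differs
            self.context_proj = (nn.ConvBNReLU(in_ch, d, 1, rng=rng)
                                 if in_ch != d else nn.Identity())
        else:
            self.context = nn.ConvBNReLU(in_ch, d, 1, rng=rng)  # after image pooling
            self.context_proj = None
        self.simam = SimAM(cfg.simam_lambda) if cfg.use_simam else None
        n_branches = 2 + len(cfg.atrous_rates)
        self.project = nn.ConvBNReLU(n_branches * d, d, 1, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        outs = [self.branch1(x)] + [m(x) for m in self.atrous]
        if self.cfg.use_strip_pool:
            outs.append(self.context_proj(self.context(x)))
        else:
            pooled = self.context(F.global_avg_pool(x))
            ones = Tensor(np.ones((1, 1, h, w), dtype=np.float32))
            outs.append(pooled * ones)       # broadcast back to the grid
        y = concat(outs, axis=1)
        if self.simam is not None:           # position B: before the 1x1 projection
            y = self.simam(y)
        return self.project(y)


def aspp_forward(high: Tensor, in_ch: int, cfg: ASPPConfig, rng=None) -> Tensor:
    """Convenience constructor+forward used by small-scale experiments."""
    return ASPP(in_ch, cfg, rng=rng)(high)
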
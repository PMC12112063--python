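"""MobileNetV2 trunk used as the profiling/calibration reference backbone.

Standard inverted-residual layout (width 1.0) without the final 1280-channel
expansion conv, as in the common DeepLabv3+ adaptations: the high-level tap
is the 320-channel block output, the low-level tap the 24-channel stride-4
features.  Strides past the requested output stride become dilated.
"""
from __future__ import annotations

from . import nn
from .backbone import FeaturePair

_SETTING = [  # expansion t, channels c, repeats n, stride s
    (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
    (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1),
]


class ReLU6(nn.Module):
    def forward(self, x):
        return x.relu() - (x - 6.0).relu()


class _ConvBNReLU6(nn.Module):
    def __init__(self, cin, cout, k, stride=1, groups=1, dilation=1, rng=None):
        super().__init__()
        pad = dilation * (k // 2)
        self.conv = nn.Conv2d(cin, cout, k, stride, pad, dilation, groups,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = ReLU6()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class InvertedResidual(nn.Module):
    def __init__(self, cin, cout, stride, expand, dilation=1, rng=None):
        super().__init__()
        hid = cin * expand
        self.use_res = stride == 1 and cin == cout
        layers = []
        if expand != 1:
            layers.append(_ConvBNReLU6(cin, hid, 1, rng=rng))
        layers.append(_ConvBNReLU6(hid, hid, 3, stride, groups=hid,
                                   dilation=dilation, rng=rng))
        proj = nn.Module()
        proj.conv = nn.Conv2d(hid, cout, 1, bias=False, rng=rng)
        proj.bn = nn.BatchNorm2d(cout)
        proj.forward = lambda x, p=proj: p.bn(p.conv(x))
        layers.append(proj)
        self.block = nn.Sequential(*layers)

    def forward(self, x):
        y = self.block(x)
        return x + y if self.use_res else y


class MobileNetV2Backbone(nn.Module):
    def __init__(self, output_stride: int = 8, rng=None):
        super().__init__()
        if output_stride not in (8, 16, 32):
            raise ValueError("output_stride must be 8, 16 or 32")
        self.output_stride = output_stride
        self.stem = _ConvBNReLU6(3, 32, 3, 2, rng=rng)
        blocks = []
        cin, stride_prod = 32, 2
        self.low_index = None
        for t, c, n, s in _SETTING:
            for i in range(n):
                s_i = s if i == 0 else 1
                dil = 1
                if s_i == 2:
                    if stride_prod * 2 > output_stride:
                        s_i, dil = 1, 2
                    else:
                        stride_prod *= 2
                blocks.append(InvertedResidual(cin, c, s_i, t, dilation=dil, rng=rng))
                cin = c
            if c == 24:
                self.low_index = len(blocks) - 1
        self.blocks = blocks
        self.out_channels = cin      # 320
        self.low_channels = 24
        self.mode = "train"          # no reparam branches; fuse() is identity

    def forward(self, x) -> FeaturePair:
        x = self.stem(x)
        low = None
        for i, b in enumerate(self.blocks):
            x = b(x)
            if i == self.low_index:
                low = x
        return FeaturePair(low, x)

    def fuse(self):
        return self
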
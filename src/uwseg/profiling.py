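"""Deterministic parameter and FLOP accounting.

FLOPs are counted layer-by-layer during a shape-real forward pass: every
convolution/linear records ``out_elements * (in_ch/groups * kh * kw + bias)``
multiply-accumulates.  The convention flag converts MACs to reported FLOPs:
``mac_as_one`` reports MACs, ``mac_as_two`` doubles them.  The flag is
calibrated once against the MobileNetV2 reference (whose published figure
only matches the doubled count) and then applied unchanged to every model.
Normalization, activations, pooling and interpolation are outside the count.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, no_grad
from .nn import functional as F

CALIBRATED_CONVENTION = "mac_as_two"


@dataclass
class ProfileReport:
    input_size: tuple
    convention: str = CALIBRATED_CONVENTION
    mode: str = "train"
    params: int = 0
    macs: int = 0
    layers: list = field(default_factory=list)

    def add(self, kind: str, params: int, macs: int):
        self.layers.append((kind, params, macs))
        self.macs += macs

    @property
    def flops(self) -> int:
        return self.macs * (2 if self.convention == "mac_as_two" else 1)

    @property
    def params_m(self) -> float:
        return round(self.params / 1e6, 3)

    @property
    def flops_g(self) -> float:
        return round(self.flops / 1e9, 3)

    def table(self) -> str:
        """Per-layer wiring audit."""
        rows = [f"{'layer':<12} {'params':>12} {'MACs':>16}"]
        for kind, p, m in self.layers:
            rows.append(f"{kind:<12} {p:>12} {m:>16}")
        rows.append(f"{'total':<12} {self.params:>12} {self.macs:>16}")
        return "\n".join(rows)


def count_params(model) -> int:
    """Number of trainable scalars."""
    return model.num_parameters()


def profile_model(model, input_size=(512, 512),
                  convention: str = CALIBRATED_CONVENTION) -> ProfileReport:
    """Run one dummy forward and collect the layer-wise MAC/param census."""
    if convention not in ("mac_as_one", "mac_as_two"):
        raise ValueError(f"unknown convention {convention!r}")
    h, w = input_size
    mode = getattr(model.backbone, "mode", "train") if hasattr(model, "backbone") \
        else getattr(model, "mode", "train")
    report = ProfileReport(input_size=(h, w), convention=convention, mode=mode)
    report.params = count_params(model)
    was_training = model.training
    model.eval()
    F._PROFILER = report
    try:
        with no_grad():
            model(Tensor(np.zeros((1, 3, h, w), dtype=np.float32)))
    finally:
        F._PROFILER = None
        model.train(was_training)
    return report


def count_flops(model, input_size=(512, 512),
                convention: str = CALIBRATED_CONVENTION) -> int:
    return profile_model(model, input_size, convention).flops
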
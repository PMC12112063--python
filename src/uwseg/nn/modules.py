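"""Module containers and the standard trainable layers."""
from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------
    def state_dict(self, prefix: str = "", out=None):
        out = {} if out is None else out
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k, b in getattr(self, "_buffers", {}).items():
            out[prefix + k] = b
        for k, m in self._modules.items():
            m.state_dict(prefix + k + ".", out)
        return out

    def load_state_dict(self, sd: dict, prefix: str = ""):
        for k, p in self._params.items():
            p.data[...] = sd[prefix + k]
        for k in getattr(self, "_buffers", {}):
            getattr(self, k)[...] = sd[prefix + k]
        for k, m in self._modules.items():
            m.load_state_dict(sd, prefix + k + ".")

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 dilation=1, groups=1, bias=True, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.padding = kernel_size, stride, padding
        self.dilation, self.groups = dilation, groups
        rng = rng or np.random.default_rng()
        fan_in = (in_ch // groups) * kernel_size ** 2
        std = math.sqrt(2.0 / fan_in)            # He init for ReLU trunks
        w = rng.normal(0.0, std, (out_ch, in_ch // groups, kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)


class BatchNorm2d(Module):
    def __init__(self, ch, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Tensor(np.ones(ch), requires_grad=True)
        self.bias = Tensor(np.zeros(ch), requires_grad=True)
        object.__setattr__(self, "_buffers", {})
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._buffers["running_mean"] = self.running_mean
        self._buffers["running_var"] = self.running_var

    def forward(self, x):
        g = self.weight.reshape(1, self.ch, 1, 1)
        b = self.bias.reshape(1, self.ch, 1, 1)
        if self.training:
            out, mu, var = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mu
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var * (n / max(n - 1, 1))
            return out
        rm = Tensor(self.running_mean.reshape(1, self.ch, 1, 1))
        inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps).reshape(1, self.ch, 1, 1))
        return (x - rm) * inv * g + b


class ConvBN(Module):
    """conv -> BN (no activation); the reparameterizable unit of a branch."""

    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 dilation=1, groups=1, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel_size, stride, padding,
                           dilation, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x))


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 dilation=1, groups=1, bias=True, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel_size, stride, padding,
                           dilation, groups, bias=bias, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()
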
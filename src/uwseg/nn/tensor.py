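"""Minimal reverse-mode autodiff over numpy arrays.

Only the operations the segmentation network needs are implemented: broadcast
arithmetic, matmul, reshape/transpose/slice/concat, reductions, relu/sigmoid/
log/exp/pow, channel-axis max.  Convolution lives in ``uwseg.nn.functional``
as a primitive with a hand-written backward.  All tensors are float32 unless
constructed otherwise.
"""
from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference/profiling)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev if _grad_enabled else ()
        self.name = name

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            if g.dtype == np.float32 and g.base is None:
                self.grad = g               # fresh array: take ownership
            else:
                self.grad = g.astype(np.float32)
        else:
            self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward):
        needs = _grad_enabled and any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=needs, _prev=prev if needs else ())
        if needs:
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self, p=p):
            if a.requires_grad:
                a._accumulate(g * p * np.power(a.data, p - 1))

        return self._make(np.power(self.data, p), (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accumulate(full)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to (all) argmax positions equally."""
        out = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g, a=self, mask=mask, counts=counts, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(mask * (g / counts))

        data = out if keepdims else out.squeeze(axis)
        return self._make(data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, mask=mask):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        from scipy.special import expit
        s = expit(self.data)

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g, a=self, e=e):
            if a.requires_grad:
                a._accumulate(g * e)

        return self._make(e, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float):
        mask = self.data > lo

        def backward(g, a=self, mask=mask):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), backward)

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._prev:                 # non-leaf: free memory eagerly
                t.grad = None
                t._backward = None
                t._prev = ()


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    needs = _grad_enabled and any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=needs, _prev=tuple(tensors) if needs else ())
    if needs:
        def backward(g):
            sl = [slice(None)] * g.ndim
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl[axis] = slice(a, b)
                    t._accumulate(g[tuple(sl)])

        out._backward = backward
    return out


def stack_mean_var(x: Tensor, axes=(2, 3)):
    """Mean and (biased) variance over ``axes`` as differentiable tensors."""
    mu = x.mean(axis=axes, keepdims=True)
    d = x - mu
    var = (d * d).mean(axis=axes, keepdims=True)
    return mu, var
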
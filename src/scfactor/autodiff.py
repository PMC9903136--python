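"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the variational objective needs: broadcasted
arithmetic, matmul, tanh/softplus/exp/log, log-gamma, axis reductions,
log-sum-exp, column slicing/concatenation, and a bounds clip.  Gradients
propagate through a topologically sorted tape; broadcasting is undone by
summing over broadcast axes.  Every primitive is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln as _gammaln, digamma as _digamma


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, g):
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            a._accum(g)
            b._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            a._accum(g)
            b._accum(-g)

        return self._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            a._accum(g / b.data)
            b._accum(-g * a.data / b.data**2)

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bwd(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            a._accum(g * o)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, a=self, o=out_data):
            a._accum(g * (1.0 - o**2))

        return self._make(out_data, (self,), bwd)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)

        def bwd(g, a=self):
            a._accum(g / (1.0 + np.exp(-a.data)))

        return self._make(out_data, (self,), bwd)

    def gammaln(self):
        def bwd(g, a=self):
            a._accum(g * _digamma(a.data))

        return self._make(_gammaln(self.data), (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only where the input is inside."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g, a=self, m=mask):
            a._accum(g * m)

        return self._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        out_data = m + np.log(np.sum(np.exp(self.data - m), axis=axis, keepdims=True))
        soft = np.exp(self.data - out_data)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bwd(g, a=self, s=soft):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(gg * s)

        return self._make(out_data, (self,), bwd)

    def cols(self, start: int, stop: int):
        """Column slice [:, start:stop] of a 2-D tensor."""
        def bwd(g, a=self):
            full = np.zeros_like(a.data)
            full[:, start:stop] = g
            a._accum(full)

        return self._make(self.data[:, start:stop], (self,), bwd)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two 2-D tensors along columns."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    na = a.data.shape[1]

    def bwd(g, a=a, b=b, na=na):
        a._accum(g[:, :na])
        b._accum(g[:, na:])

    return a._make(np.concatenate([a.data, b.data], axis=1), (a, b), bwd)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
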
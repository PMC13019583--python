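"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the negative-binomial autoencoder,
attention pooling, classification heads and integrated-gradients
attribution require: elementwise arithmetic with broadcasting, matrix
products, the usual nonlinearities, ``log-gamma`` (whose derivative is the
digamma function), reductions and basic indexing.  Gradients are
accumulated by a topological sweep over the recorded computation graph.

The engine is dtype-preserving: float32 graphs stay float32 (training),
float64 graphs stay float64 (gradient checks).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = ["Tensor", "Parameter", "Adam", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make ndarray <op> Tensor dispatch to the Tensor reflected operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward: Callable[[], None] = lambda: None
        self._prev = _prev

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return self.data.item()

    def _wrap(self, other) -> "Tensor":
        """Coerce a non-Tensor operand, keeping this tensor's dtype."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.dtype))

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()

    # -- elementwise arithmetic -----------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = _backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _backward
        return out

    # -- linear algebra --------------------------------------------------
    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _backward():
            g = out.grad
            a, b = self.data, other.data
            # promote 1-D operands to the matrix view numpy's @ implies
            g2 = g.reshape(a.shape[0] if a.ndim == 2 else 1, -1)
            a2 = a.reshape(1, -1) if a.ndim == 1 else a
            b2 = b.reshape(-1, 1) if b.ndim == 1 else b
            if self.requires_grad:
                self._accum((g2 @ b2.T).reshape(a.shape))
            if other.requires_grad:
                other._accum((a2.T @ g2).reshape(b.shape))

        out._backward = _backward
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = _backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = _backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _backward
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _backward
        return out

    def log1p(self) -> "Tensor":
        out = Tensor(np.log1p(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad / (1.0 + self.data))

        out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        out._backward = _backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        s = expit(self.data)
        out = Tensor(s, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _backward
        return out

    def softplus(self) -> "Tensor":
        out = Tensor(np.logaddexp(0.0, self.data).astype(self.dtype), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * expit(self.data))

        out._backward = _backward
        return out

    def lgamma(self) -> "Tensor":
        out = Tensor(gammaln(self.data).astype(self.dtype), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * digamma(self.data).astype(self.dtype))

        out._backward = _backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))

        def _backward():
            if self.requires_grad:
                mask = (self.data >= lo) & (self.data <= hi)
                self._accum(out.grad * mask)

        out._backward = _backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A tensor that is optimized: ``requires_grad`` is always on."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.array(data), requires_grad=True)


class Adam:
    """Adam optimizer with optional per-group learning rates.

    ``groups`` is a list of ``(params, lr)`` pairs; a flat parameter list
    with a single ``lr`` is also accepted.
    """

    def __init__(
        self,
        params: Sequence[Parameter] | None = None,
        lr: float = 1e-3,
        groups: Sequence[tuple[Sequence[Parameter], float]] | None = None,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if groups is None:
            groups = [(list(params or []), lr)]
        self.groups = [(list(ps), g_lr) for ps, g_lr in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for ps, _ in self.groups:
            for p in ps:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for ps, _ in self.groups:
            for p in ps:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for ps, lr in self.groups:
            for p in ps:
                if p.grad is None:
                    continue
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= self.b1
                m += (1.0 - self.b1) * p.grad
                v *= self.b2
                v += (1.0 - self.b2) * p.grad**2
                p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
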
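"""Minimal reverse-mode automatic differentiation over numpy arrays.

The graph-classification models in this package need trainable GCN and
attention layers, and no deep-learning framework is assumed to be
available at run time.  This module provides the small set of
differentiable operations those layers require: broadcast arithmetic,
matrix products, element-wise nonlinearities, reductions, reshaping and
concatenation.  Gradients flow only through :class:`Tensor` operands;
plain numpy arrays mixed into an expression are treated as constants.

The engine is eager and single-threaded, which together with seeded
initialization makes training bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing --------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic ------------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        out_data = a.data + b.data

        def backward() -> None:
            a._accumulate(_unbroadcast(out.grad, a.shape))
            b._accumulate(_unbroadcast(out.grad, b.shape))

        out = self._make(out_data, (a, b), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        out_data = a.data * b.data

        def backward() -> None:
            a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
            b._accumulate(_unbroadcast(out.grad * a.data, b.shape))

        out = self._make(out_data, (a, b), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        out_data = a.data / b.data

        def backward() -> None:
            a._accumulate(_unbroadcast(out.grad / b.data, a.shape))
            b._accumulate(_unbroadcast(-out.grad * a.data / b.data ** 2, b.shape))

        out = self._make(out_data, (a, b), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        a, b = self, self._lift(other)
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2D operands; reshape first")
        out_data = a.data @ b.data

        def backward() -> None:
            a._accumulate(out.grad @ b.data.T)
            b._accumulate(a.data.T @ out.grad)

        out = self._make(out_data, (a, b), backward)
        return out

    # -- nonlinearities --------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward() -> None:
            self._accumulate(out.grad * mask)

        out = self._make(out_data, (self,), backward)
        return out

    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, negative_slope)
        out_data = self.data * slope

        def backward() -> None:
            self._accumulate(out.grad * slope)

        out = self._make(out_data, (self,), backward)
        return out

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward() -> None:
            self._accumulate(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward() -> None:
            self._accumulate(out.grad / self.data)

        out = self._make(out_data, (self,), backward)
        return out

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward() -> None:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int = 0) -> "Tensor":
        """Max over one axis; gradient routes to the (first) argmax."""
        arg = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis)

        def backward() -> None:
            g = np.zeros_like(self.data)
            idx = list(np.indices(out_data.shape))
            idx.insert(axis, arg)
            g[tuple(idx)] = out.grad
            self._accumulate(g)

        out = self._make(out_data, (self,), backward)
        return out

    # -- shape -----------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward() -> None:
            self._accumulate(out.grad.reshape(self.shape))

        out = self._make(out_data, (self,), backward)
        return out

    @property
    def T(self) -> "Tensor":
        out_data = self.data.T

        def backward() -> None:
            self._accumulate(out.grad.T)

        out = self._make(out_data, (self,), backward)
        return out

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward() -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, key, out.grad)
            self._accumulate(g)

        out = self._make(out_data, (self,), backward)
        return out

    # -- composite helpers -----------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        shift = self - self.data.max(axis=axis, keepdims=True)  # constant shift
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shift = self - self.data.max(axis=axis, keepdims=True)
        return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out_data.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
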
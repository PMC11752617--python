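"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the model is trained with: a small tensor type
recording a computation graph, plus the handful of differentiable operations
the architecture needs (broadcasting arithmetic, batched matmul, exp/log,
ELU, reductions, softmax, gather and concatenation).  Gradients are exact
(verified against central differences in the test suite) and everything is
float64 for run-to-run bit reproducibility.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "elu",
    "exp",
    "log",
    "matmul",
    "softmax",
    "take",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the same upstream buffer may feed several parents
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    # -- shape ops ------------------------------------------------------------

    def transpose(self, *axes: int) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inverse = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.transpose(g, inverse))

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- misc -----------------------------------------------------------------

    def frobenius_sq(self) -> "Tensor":
        """Squared Frobenius norm, summed over all entries."""
        return (self * self).sum()

    def norm(self) -> "Tensor":
        return self.frobenius_sq() ** 0.5


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(out_data, (a, b), backward)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * out_data)

    return Tensor._make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = as_tensor(x)
    out_data = np.where(x.data > 0, x.data, alpha * np.expm1(x.data))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, out_data + alpha))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax along `axis`."""
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant; grad-free
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    return Tensor._make(out_data, ts, backward)


def gauss_kernel_sum(x: Tensor, y: Tensor) -> Tensor:
    """Sum of the Gaussian kernel exp(-||x_i - y_j||^2 / 2) over all pairs.

    Samples are columns for 2-D inputs (features x n); for 3-D inputs the
    layout is batched rows (batch x n x features) and the sum runs over all
    batches and pairs.  A fused op: the kernel matrix is built once in the
    forward pass and reused for the analytic gradient.
    """
    x, y = as_tensor(x), as_tensor(y)
    if x.ndim == 2:
        xs, ys = x.data.T, y.data.T          # samples on rows
    elif x.ndim == 3:
        xs, ys = x.data, y.data
    else:
        raise ValueError("expected 2-D or 3-D inputs")
    x2 = (xs * xs).sum(axis=-1)
    y2 = (ys * ys).sum(axis=-1)
    cross = xs @ np.swapaxes(ys, -1, -2)
    d2 = x2[..., :, np.newaxis] + y2[..., np.newaxis, :] - 2.0 * cross
    kmat = np.exp(-0.5 * d2)
    out_data = np.array(kmat.sum())

    def backward(g: np.ndarray) -> None:
        gs = float(g)
        if x.requires_grad:
            gx = gs * (kmat @ ys - xs * kmat.sum(axis=-1)[..., :, np.newaxis])
            x._accumulate(gx.T if x.ndim == 2 else gx)
        if y.requires_grad:
            gy = gs * (np.swapaxes(kmat, -1, -2) @ xs
                       - ys * kmat.sum(axis=-2)[..., :, np.newaxis])
            y._accumulate(gy.T if y.ndim == 2 else gy)

    return Tensor._make(out_data, (x, y), backward)


def take(x: Tensor, indices: np.ndarray, axis: int = 0) -> Tensor:
    """Gather slices of `x` along `axis` with an arbitrary index array."""
    x = as_tensor(x)
    indices = np.asarray(indices)
    out_data = np.take(x.data, indices, axis=axis)

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        moved = np.moveaxis(gx, axis, 0)
        g_moved = np.moveaxis(
            g, tuple(range(axis, axis + indices.ndim)), tuple(range(indices.ndim)))
        np.add.at(moved, indices, g_moved)
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)
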
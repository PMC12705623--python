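"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's neural components need:
dense linear algebra, pointwise nonlinearities, row gather / segment
scatter-add (the primitives of message passing on edge lists), and
concatenation. Gradients use float64 throughout; graphs here are small
enough that clarity and determinism beat raw speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
    "softmax",
    "Linear",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce `grad` back to `shape` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: an ndarray plus its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = True, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._prev = _prev
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        """Add `grad` into this tensor's gradient.

        `own=True` promises the caller freshly allocated `grad` for this
        tensor alone, letting us adopt the buffer instead of copying.
        """
        if not self.requires_grad:
            return
        if self.grad is None:
            if own and grad.shape == self.data.shape:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=np.float64)
                if self.grad.shape != self.data.shape:
                    self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    # ---- arithmetic -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=np.float64), requires_grad=False)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def back():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self._accum(-out.grad, own=True)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def back():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape), own=True)
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape), own=True)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def back():
            self._accum(_unbroadcast(out.grad / other.data, self.data.shape), own=True)
            other._accum(
                _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape),
                own=True,
            )

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def back():
            self._accum(out.grad @ other.data.T, own=True)
            other._accum(self.data.T @ out.grad, own=True)

        out._backward = back
        return out

    __matmul__ = matmul

    # ---- pointwise --------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * out.data, own=True)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad / self.data, own=True)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * 0.5 / out.data, own=True)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * (self.data > 0), own=True)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * out.data * (1.0 - out.data), own=True)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda: self._accum(out.grad * (1.0 - out.data**2), own=True)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the interval."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda: self._accum(out.grad * mask, own=True)
        return out

    # ---- reductions & shaping ---------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    # ---- autodiff driver --------------------------------------------

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()
            # tear down the tape: break closure cycles so buffers free
            # promptly, and drop intermediate grads (leaves keep theirs)
            if t._prev:
                t._backward = None
                t._prev = ()
                if t is not self:
                    t.grad = None

    def detach(self) -> np.ndarray:
        return self.data.copy()


# ---- structural ops -------------------------------------------------


def _segment_reduce(values: np.ndarray, idx: np.ndarray, n: int,
                    ufunc, fill: float) -> np.ndarray:
    """Reduce rows of `values` into `n` buckets via sort + reduceat
    (much faster than ufunc.at for repeated indices)."""
    out_shape = (n,) + values.shape[1:]
    if len(idx) == 0:
        return np.full(out_shape, fill)
    if np.any(np.diff(idx) < 0):
        perm = np.argsort(idx, kind="stable")
        idx = idx[perm]
        values = values[perm]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(idx)) + 1])
    flat = np.ascontiguousarray(values.reshape(len(idx), -1))
    sums = ufunc.reduceat(flat, starts, axis=0)
    out = np.full((n, flat.shape[1]), fill)
    out[idx[starts]] = sums
    return out.reshape(out_shape)


def _scatter_add(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    return _segment_reduce(values, idx, n, np.add, 0.0)


def concat(tensors: list, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(idx)])

    out._backward = back
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows `idx` (with repetition) from a 1-D or 2-D tensor."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], _prev=(t,))
    out._backward = lambda: t._accum(_scatter_add(out.grad, idx, len(t.data)), own=True)
    return out


def segment_sum(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=np.intp)
    out = Tensor(_scatter_add(t.data, segments, num_segments), _prev=(t,))
    out._backward = lambda: t._accum(out.grad[segments], own=True)
    return out


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D or (E,1) score tensor within each segment.

    The per-segment max is subtracted as a constant for numerical
    stability, which leaves the gradient unchanged.
    """
    segments = np.asarray(segments, dtype=np.intp)
    flat = scores.data.reshape(len(segments), -1)
    mx = _segment_reduce(flat, segments, num_segments, np.maximum, -np.inf)
    shift = Tensor(mx[segments].reshape(scores.data.shape), requires_grad=False)
    e = (scores - shift).exp()
    denom = segment_sum(e, segments, num_segments)
    return e / gather_rows(denom, segments)


def softmax(t: Tensor, axis: int = 1) -> Tensor:
    mx = Tensor(t.data.max(axis=axis, keepdims=True), requires_grad=False)
    e = (t - mx).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---- parameters and optimizer ---------------------------------------


class Linear:
    """Dense layer y = xW (+ b), Glorot-initialized from an explicit rng."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Tensor(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list:
        return [self.W] if self.b is None else [self.W, self.b]


class Adam:
    """Adaptive-moment optimizer with the standard bias correction."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
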
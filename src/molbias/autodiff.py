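"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-free, graph-walking autodiff: every :class:`Tensor` remembers its
parents and a closure that propagates the adjoint. The op set is exactly
what a message-passing network with gated recurrent updates, attention
readouts and optimal-transport costs needs — dense linear algebra,
pointwise nonlinearities, reductions, concatenation, row gather and
segment (scatter-add) sums. All arithmetic is float64.

Broadcasting follows numpy semantics; adjoints of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "sqrt",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))

        def backward(g):
            self._accum(g.T)

        out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if id(node) in seen:
                continue
            if processed:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out


# ------------------------------------------------------------------ pointwise
def relu(t: Tensor) -> Tensor:
    out = Tensor(np.maximum(t.data, 0.0), parents=(t,))
    out._backward = lambda g: t._accum(g * (t.data > 0))
    return out


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(t.data, -60, 60)))
    out = Tensor(s, parents=(t,))
    out._backward = lambda g: t._accum(g * s * (1.0 - s))
    return out


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)
    out = Tensor(y, parents=(t,))
    out._backward = lambda g: t._accum(g * (1.0 - y * y))
    return out


def exp(t: Tensor) -> Tensor:
    y = np.exp(np.clip(t.data, -700, 700))
    out = Tensor(y, parents=(t,))
    out._backward = lambda g: t._accum(g * y)
    return out


def log(t: Tensor) -> Tensor:
    out = Tensor(np.log(t.data), parents=(t,))
    out._backward = lambda g: t._accum(g / t.data)
    return out


def sqrt(t: Tensor) -> Tensor:
    y = np.sqrt(t.data)
    out = Tensor(y, parents=(t,))
    out._backward = lambda g: t._accum(g * 0.5 / np.maximum(y, 1e-300))
    return out


# ----------------------------------------------------------------- structural
def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]``; adjoint scatter-adds back."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], parents=(t,))

    def backward(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accum(full)

    out._backward = backward
    return out


def segment_sum(t: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given by ``seg``."""
    seg = np.asarray(seg, dtype=np.intp)
    data = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(data, seg, t.data)
    out = Tensor(data, parents=(t,))
    out._backward = lambda g: t._accum(g[seg])
    return out


# ------------------------------------------------------------------ optimizer
class Adam:
    """Adam optimizer over a dict of named parameter tensors (no weight decay)."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored loss has
    not improved for ``patience`` consecutive epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.7, patience: int = 5, min_lr: float = 0.0):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self._best = np.inf
        self._bad_epochs = 0

    def step(self, loss: float):
        if loss < self._best - 1e-12:
            self._best = loss
            self._bad_epochs = 0
        else:
            self._bad_epochs += 1
            if self._bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self._bad_epochs = 0
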
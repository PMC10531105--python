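"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's small sequence models need:
broadcasting arithmetic, (batched) matmul, elementwise nonlinearities,
reductions, reshaping/indexing, stable softmax/log-softmax, stack/concat.
Gradients accumulate only into leaf tensors created with requires_grad=True
(the model parameters).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "stack", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient produced under broadcasting back to `shape`."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._node(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._node(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._node(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._node(
            a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)
            return ga, gb

        return Tensor._node(a.data @ b.data, (a, b), backward)

    # -- nonlinearities ------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._node(
            out_data, (self,), lambda g: (g * out_data * (1 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: (g * mask,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._node(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for i in sorted(ax):
                    g = np.expand_dims(g, i if i >= 0 else i + a.data.ndim)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data).astype(np.float64)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * mask,)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._node(data, (a,), backward)

    # -- shape / indexing ----------------------------------------------------

    def reshape(self, *shape):
        a = self
        return Tensor._node(
            a.data.reshape(*shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(range(a.data.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor._node(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, key):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._node(a.data[key], (a,), backward)

    # -- stable softmax family -----------------------------------------------

    def log_softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g):
            return (g - soft * g.sum(axis=axis, keepdims=True),)

        return Tensor._node(out_data, (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

        return Tensor._node(s, (a,), backward)

    # -- engine ----------------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack_.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._node(data, tensors, backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._node(data, tensors, backward)


class Adam:
    """Standard Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
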
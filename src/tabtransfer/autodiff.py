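"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (a few encoder blocks on at most a few
dozen feature tokens), so a tape-based engine over float64 NumPy arrays is
fast enough for training and keeps every numerical step inspectable.  Only
the primitives the model needs are implemented: broadcast arithmetic,
(batched) matrix products, reductions, ``relu``/``exp``/``log``,
numerically stable ``softplus`` and ``log_softmax``, row gathering for
embedding lookups, concatenation, slicing, transposition and reshaping.

Gradient correctness is guarded by finite-difference checks in the test
suite rather than assumed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather",
    "log_softmax",
    "softmax",
    "softplus",
    "sigmoid",
    "layer_norm",
    "dropout",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that NumPy broadcasting introduced."""
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            self._accumulate(
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
            )
            other._accumulate(
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
            )

        return Tensor(
            np.matmul(self.data, other.data), parents=(self, other), backward=backward
        )

    # -- shape ops -----------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.data, a, b), parents=(self,), backward=backward)

    def transpose(self, *axes: int) -> "Tensor":
        axes_ = axes or tuple(reversed(range(self.ndim)))
        inverse = np.argsort(axes_)

        def backward(g: np.ndarray) -> None:
            self._accumulate(np.transpose(g, inverse))

        return Tensor(np.transpose(self.data, axes_), parents=(self,), backward=backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor(self.data[key], parents=(self,), backward=backward)

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
            backward=backward,
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities ------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def gather(table: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``table[index]`` (embedding lookup); grad scatter-adds."""
    index = np.asarray(index)
    if not np.issubdtype(index.dtype, np.integer):
        raise TypeError("gather index must be integer")

    def backward(g: np.ndarray) -> None:
        full = np.zeros_like(table.data)
        np.add.at(full, index, g)
        table._accumulate(full)

    return Tensor(table.data[index], parents=(table,), backward=backward)


def softplus(x: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, x.data)

    def backward(g: np.ndarray) -> None:
        x._accumulate(g / (1.0 + np.exp(-x.data)))

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    out_data = shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))

    def backward(g: np.ndarray) -> None:
        soft = np.exp(out_data)
        x._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / ((var + eps) ** 0.5) * gamma + beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity in evaluation mode."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


class Adam:
    """Adam over a named parameter dict; parameters in ``frozen`` are skipped."""

    def __init__(
        self,
        params: Mapping[str, Tensor],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        frozen: Iterable[str] = (),
    ):
        self.params = dict(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.frozen = frozenset(frozen)
        self._m = {k: np.zeros_like(t.data) for k, t in self.params.items()}
        self._v = {k: np.zeros_like(t.data) for k, t in self.params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for name, tensor in self.params.items():
            if name in self.frozen or tensor.grad is None:
                continue
            g = tensor.grad
            self._m[name] = b1 * self._m[name] + (1 - b1) * g
            self._v[name] = b2 * self._v[name] + (1 - b2) * g * g
            m_hat = self._m[name] / (1 - b1**self._t)
            v_hat = self._v[name] / (1 - b2**self._t)
            tensor.data = tensor.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
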
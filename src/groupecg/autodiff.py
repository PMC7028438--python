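"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
records how it was produced; :meth:`Tensor.backward` walks the tape in
reverse topological order accumulating gradients.  Only the operations the
ECG model needs are implemented (elementwise arithmetic, matmul, 1-D
convolution and pooling, reductions, slicing, concatenation and the usual
activations).  Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "sigmoid", "tanh", "relu", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the recipe for its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}{tag}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph construction --------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def broadcast_to(self, shape):
        def backward(g):
            self._accum(_unbroadcast(g, self.shape))

        return self._make(np.broadcast_to(self.data, shape).copy(), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g / (2.0 * out_data))

        return self._make(out_data, (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo (ties get zero)."""
        mask = self.data > lo

        def backward(g):
            self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor with requires_grad=False")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion would overflow on long sequences
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad_tree(self) -> None:
        for node in self._iter_graph():
            node.grad = None

    def _iter_graph(self) -> Iterable["Tensor"]:
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            yield node
            stack.extend(node._parents)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


# -- free functions -----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - out_data ** 2))

    return x._make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return x._make(x.data * mask, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # Shift by the (detached) max: softmax is shift-invariant, so the
    # gradient of the shift is exactly zero and detaching it is lossless.
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- 1-D convolution / pooling primitives -------------------------------------

def _gather_columns(xp: np.ndarray, kernel: int, stride: int, dilation: int,
                    out_len: int) -> tuple[np.ndarray, np.ndarray]:
    """im2col for [N, C, Lp] arrays → cols [N, C, K, T_out] and the index map."""
    idx = (np.arange(kernel) * dilation)[:, None] + (np.arange(out_len) * stride)[None, :]
    return xp[:, :, idx], idx


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, dilation: int = 1, padding: str | int = "same") -> Tensor:
    """Temporal convolution of ``x`` [N, C_in, L] with ``weight`` [C_out, C_in, K].

    ``padding="same"`` keeps ``ceil(L / stride)`` output samples.
    """
    n, c_in, length = x.shape
    c_out, c_in_w, kernel = weight.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input {c_in} vs weight {c_in_w}")
    if length == 0:
        raise ValueError("zero-length input to conv1d")
    span = (kernel - 1) * dilation + 1
    if padding == "same":
        out_len = -(-length // stride)
        total = max(0, (out_len - 1) * stride + span - length)
        left, right = total // 2, total - total // 2
    else:
        left = right = int(padding)
        out_len = (length + left + right - span) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right)))
    cols, idx = _gather_columns(xp, kernel, stride, dilation, out_len)
    out_data = np.einsum("nckt,ock->not", cols, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if x.requires_grad:
            dcols = np.einsum("not,ock->nckt", g, weight.data, optimize=True)
            dxp = np.zeros_like(xp)
            np.add.at(dxp, (slice(None), slice(None), idx), dcols)
            x._accum(dxp[:, :, left:left + length])
        if weight.requires_grad:
            weight._accum(np.einsum("not,nckt->ock", g, cols, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))

    return x._make(out_data, parents, backward)


def avg_pool1d(x: Tensor, kernel: int, stride: int = 1) -> Tensor:
    """Average pooling with "same" zero padding; zeros count toward the mean."""
    n, c, length = x.shape
    out_len = -(-length // stride)
    total = max(0, (out_len - 1) * stride + kernel - length)
    left = total // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, total - left)))
    cols, idx = _gather_columns(xp, kernel, stride, 1, out_len)
    out_data = cols.mean(axis=2)

    def backward(g):
        dxp = np.zeros_like(xp)
        np.add.at(dxp, (slice(None), slice(None), idx), np.broadcast_to(
            g[:, :, None, :] / kernel, (n, c, kernel, out_len)))
        x._accum(dxp[:, :, left:left + length])

    return x._make(out_data, (x,), backward)
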
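"""Reverse-mode autodiff on numpy arrays.

Operations record closures on a tape; :meth:`Tensor.backward` replays the
tape in reverse topological order. Gradients accumulate into ``.grad`` of
every tensor created with ``requires_grad=True`` (and of intermediates
that depend on one). A module-level switch (:func:`no_grad`) disables tape
construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(_parents) if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            raise NotImplementedError("division only by python scalars")
        return self * (1.0 / float(other))

    # -- matmul ---------------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        src_shape = self.data.shape
        out._backward = lambda g: self._accum(g.reshape(src_shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        inv = np.argsort(axes)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        src_shape = self.data.shape

        def _bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, src_shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, src_shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def gelu(self) -> "Tensor":
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=np.float32)))
        out_data = (x * phi).astype(np.float32)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        pdf = (np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)).astype(np.float32)
        local = (phi + x * pdf).astype(np.float32)
        out._backward = lambda g: self._accum(g * local)
        return out

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(s)
        out = Tensor(s, True, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def log(self, eps: float = 1e-12) -> "Tensor":
        """Natural log with the argument clamped at ``eps``."""
        x = np.clip(self.data, eps, None)
        out_data = np.log(x)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accum(g / x)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(s)
        out = Tensor(s, True, (self,))

        def _bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = _bw
        return out

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Layer normalization over the last axis with affine parameters."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = ((x - mu) * inv).astype(np.float32)
        out_data = xhat * weight.data + bias.data
        req = self.requires_grad or weight.requires_grad or bias.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, weight, bias))

        def _bw(g):
            if weight.requires_grad:
                axes = tuple(range(g.ndim - 1))
                weight._accum((g * xhat).sum(axis=axes))
            if bias.requires_grad:
                axes = tuple(range(g.ndim - 1))
                bias._accum(g.sum(axis=axes))
            if self.requires_grad:
                dxhat = g * weight.data
                m1 = dxhat.mean(axis=-1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
                self._accum((inv * (dxhat - m1 - xhat * m2)).astype(np.float32))

        out._backward = _bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; caller decides train/eval (eval: don't call)."""
        if rate <= 0.0:
            return self
        keep = 1.0 - rate
        mask = (rng.random(self.data.shape) < keep).astype(np.float32) / keep
        return self * Tensor(mask)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = _bw
    return out


def bce_with_logits(
    logits: Tensor,
    targets: np.ndarray,
    pos_weight: Optional[np.ndarray] = None,
) -> Tensor:
    """Weighted binary cross-entropy on logits, mean-reduced over all entries.

    Per entry: ``-[w·y·log p + (1-y)·log(1-p)]`` with ``p = sigmoid(logit)``
    and log arguments clamped at 1e-12. ``pos_weight`` broadcasts over the
    batch (one weight per label); ``None`` means all ones.
    """
    if not np.all(np.isfinite(logits.data)):
        raise FloatingPointError("non-finite logits passed to bce_with_logits")
    # loss value in float64 so it agrees with a reference implementation
    # to ~1e-12 on the same float32 logits; gradients stay float32
    z = logits.data.astype(np.float64)
    y = np.asarray(targets, dtype=np.float64)
    w = np.ones_like(y) if pos_weight is None else np.broadcast_to(
        np.asarray(pos_weight, dtype=np.float64), y.shape
    )
    p = 1.0 / (1.0 + np.exp(-np.abs(z)))
    p = np.where(z >= 0, p, 1.0 - p)
    eps = 1e-12
    ll = -(w * y * np.log(np.clip(p, eps, None))
           + (1.0 - y) * np.log(np.clip(1.0 - p, eps, None)))
    out_data = np.float64(ll.mean())
    if not (logits.requires_grad and _GRAD_ENABLED):
        out = Tensor(0.0)
        out.data = np.asarray(out_data)
        return out
    out = Tensor(0.0, True, (logits,))
    out.data = np.asarray(out_data)
    n = y.size

    def _bw(g):
        gz = ((1.0 - y) * p - w * y * (1.0 - p)) / n
        logits._accum(np.float32(g) * gz.astype(np.float32))

    out._backward = _bw
    return out
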
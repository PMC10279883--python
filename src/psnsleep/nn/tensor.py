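"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: float64 throughout, 2-D matmul,
elementwise ops with broadcasting, reductions, basic-slice indexing, and
two convolution-specific primitives (``conv1d``, ``max_pool1d``) with
hand-derived adjoints.  Everything the Siamese trainer differentiates is
built from these.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of graph nodes ------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basics ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autograd driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior graph state; leaves keep their grads
                node._backward = None
                node._parents = ()

    def _accum(self, g: np.ndarray):
        # accumulation always allocates; gradients are never mutated in place
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            if a.requires_grad:
                a._accum(g * e * np.power(a.data, e - 1.0))

        return Tensor._result(np.power(a.data, e), (a,), backward)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._coerce(other)
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._result(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data * out_data))

        return Tensor._result(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._result(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._result(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        inverse = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inverse))

        return Tensor._result(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[key] = g
                a._accum(full)

        return Tensor._result(a.data[key], (a,), backward)


# -- convolution primitives --------------------------------------------------

def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """1-D cross-correlation: x (B, Cin, L), weight (Cout, Cin, K) -> (B, Cout, Lout)."""
    pl, pr = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x.data
    B, Ci, Lp = xp.shape
    Co, Ci2, K = weight.data.shape
    if Ci2 != Ci:
        raise ValueError(f"channel mismatch: input {Ci}, weight {Ci2}")
    Lo = (Lp - K) // stride + 1
    if Lo < 1:
        raise ValueError(f"kernel {K} longer than padded input {Lp}")
    s0, s1, s2 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(B, Ci, Lo, K), strides=(s0, s1, s2 * stride, s2))
    cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(B * Lo, Ci * K)
    wmat = weight.data.reshape(Co, Ci * K)
    out = (cols @ wmat.T + bias.data).reshape(B, Lo, Co).transpose(0, 2, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lo, Co)
        if weight.requires_grad:
            weight._accum((g2.T @ cols).reshape(Co, Ci, K))
        if bias.requires_grad:
            bias._accum(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ wmat).reshape(B, Lo, Ci, K).transpose(0, 2, 1, 3)
            gxp = np.zeros((B, Ci, Lp))
            for k in range(K):
                gxp[:, :, k:k + stride * Lo:stride] += gcols[:, :, :, k]
            x._accum(gxp[:, :, pl:Lp - pr] if (pl or pr) else gxp)

    return Tensor._result(out, (x, weight, bias), backward)


def max_pool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling along the last axis; trailing remainder dropped."""
    B, C, L = x.data.shape
    Lk = L // kernel
    if Lk < 1:
        raise ValueError(f"pool kernel {kernel} exceeds length {L}")
    xr = x.data[:, :, :Lk * kernel].reshape(B, C, Lk, kernel)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gxr = np.zeros((B, C, Lk, kernel))
            np.put_along_axis(gxr, idx[..., None], g[..., None], axis=-1)
            full = np.zeros_like(x.data)
            full[:, :, :Lk * kernel] = gxr.reshape(B, C, Lk * kernel)
            x._accum(full)

    return Tensor._result(out, (x,), backward)
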
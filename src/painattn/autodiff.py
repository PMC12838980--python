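"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the primitives the dual-attention CNN needs:
broadcast arithmetic, matmul, 3x3 "same" convolution, 2x2 max-pooling,
elementwise nonlinearities and axis reductions. Gradients flow through a
dynamically recorded tape; ``Tensor.backward`` runs a topological sweep.

All heavy lifting (convolution, linear layers) is expressed as BLAS calls
(`np.tensordot`/`@`) on float32 arrays so single-CPU training of small
networks stays practical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if grad.shape[ax] != n:  # n == 1 here
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1.0))

        return self._make(a.data ** e, (a,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (a,), backward)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not a.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            a._accumulate(full)

        return self._make(out_data, (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(*inv))

        return self._make(a.data.transpose(*axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``; gradient is split back."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int = 1) -> Tensor:
    """2-D convolution, stride 1, square kernel, NCHW layout.

    Implemented as one tensordot per kernel tap so both directions run as
    large BLAS products (kernel is 3x3 here, so 9 taps).
    """
    N, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    p = padding
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    xpad = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out_data = np.zeros((N, O, Ho, Wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            patch = xpad[:, :, ki:ki + Ho, kj:kj + Wo]
            # (N,C,Ho,Wo) x (O,C) -> (N,Ho,Wo,O)
            out_data += np.tensordot(patch, weight.data[:, :, ki, kj],
                                     axes=([1], [1])).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data += bias.data.reshape(1, O, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data)
    if any(t.requires_grad for t in parents):
        out.requires_grad = True
        out._parents = parents

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.empty_like(weight.data)
                for ki in range(kh):
                    for kj in range(kw):
                        patch = xpad[:, :, ki:ki + Ho, kj:kj + Wo]
                        # (N,O,Ho,Wo) x (N,C,Ho,Wo) over N,Ho,Wo -> (O,C)
                        dw[:, :, ki, kj] = np.tensordot(
                            g, patch, axes=([0, 2, 3], [0, 2, 3]))
                weight._accumulate(dw)
            if x.requires_grad:
                dxpad = np.zeros_like(xpad)
                for ki in range(kh):
                    for kj in range(kw):
                        # (N,O,Ho,Wo) x (O,C) -> (N,Ho,Wo,C)
                        dxpad[:, :, ki:ki + Ho, kj:kj + Wo] += np.tensordot(
                            g, weight.data[:, :, ki, kj], axes=([1], [0])
                        ).transpose(0, 3, 1, 2)
                x._accumulate(dxpad[:, :, p:p + H, p:p + W] if p else dxpad)

        out._backward = backward
    return out


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling (NCHW); H and W must divide ``size``."""
    N, C, H, W = x.data.shape
    if H % size or W % size:
        raise ValueError(f"spatial dims {(H, W)} not divisible by pool size {size}")
    Ho, Wo = H // size, W // size
    windows = x.data.reshape(N, C, Ho, size, Wo, size).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(N, C, Ho, Wo, size * size)
    idx = np.argmax(windows, axis=-1)
    out = Tensor(np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0])
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            dwin = np.zeros((N, C, Ho, Wo, size * size), dtype=np.float32)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            dx = dwin.reshape(N, C, Ho, Wo, size, size).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(dx.reshape(N, C, H, W))

        out._backward = backward
    return out
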
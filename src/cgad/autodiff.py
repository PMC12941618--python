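"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small convolutional and multilayer networks on CPU; this
module supplies the tape. A :class:`Tensor` wraps a float64 ``numpy`` array
and records, for every differentiable operation, a closure that accumulates
gradients into its inputs. Calling :meth:`Tensor.backward` on a scalar runs
the closures in reverse topological order.

Only the operations the networks in this package need are implemented:
elementwise arithmetic with numpy broadcasting, matmul, exp/log/sqrt,
relu/sigmoid/tanh, axis reductions, reshape/transpose, concatenation,
2-D (dilated) convolution and 2x2 max pooling. Everything is float64;
the scale of the models here makes float32 economies irrelevant.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "conv2d", "maxpool2x2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer mixed ndarray/Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = tuple(p for p in _prev if p.requires_grad)

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**exponent, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # -- elementwise nonlinearities ------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        out._backward = _bw
        return out

    # -- reductions and shape ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self) -> "Tensor":
        if self.data.ndim != 2:
            raise ValueError("transpose() supports 2-D tensors only")
        out = Tensor(self.data.T, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = _bw
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(lo), int(hi))
                t._accumulate(g[tuple(idx)])

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 2-D convolution, NCHW layout, square odd kernels.

    Dilation d with kernel k pads by d*(k-1)//2 so spatial size is preserved
    (the resolution-preservation contract the context modules rely on).
    """
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Ci}")
    if kh != kw or kh % 2 == 0:
        raise ValueError("square odd kernels only")
    pad = dilation * (kh - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    taps = [(r * dilation, c * dilation) for r in range(kh) for c in range(kw)]
    cols = np.empty((N, C, len(taps), H * W), dtype=np.float64)
    for i, (rr, cc) in enumerate(taps):
        cols[:, :, i, :] = xp[:, :, rr : rr + H, cc : cc + W].reshape(N, C, H * W)
    cols2 = cols.reshape(N, C * kh * kw, H * W)
    w2 = w.data.reshape(Co, C * kh * kw)
    out_data = np.matmul(w2, cols2).reshape(N, Co, H, W)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        g2 = g.reshape(N, Co, H * W)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            # (Co, C*k*k) = sum_N (Co, HW) @ (HW, C*k*k)
            gw = np.einsum("noh,nmh->om", g2, cols2)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            # (N, C*k*k, HW)
            gcols = np.matmul(w2.T, g2).reshape(N, C, len(taps), H * W)
            gxp = np.zeros_like(xp)
            for i, (rr, cc) in enumerate(taps):
                gxp[:, :, rr : rr + H, cc : cc + W] += gcols[:, :, i, :].reshape(N, C, H, W)
            x._accumulate(gxp[:, :, pad : pad + H, pad : pad + W])

    out._backward = _bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial sizes must be even."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    h2, w2 = H // 2, W // 2
    patches = (
        x.data.reshape(N, C, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, h2, w2, 4)
    )
    idx = patches.argmax(axis=-1)
    out = Tensor(np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gp = np.zeros((N, C, h2, w2, 4), dtype=np.float64)
        np.put_along_axis(gp, idx[..., None], g[..., None], axis=-1)
        gx = gp.reshape(N, C, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        x._accumulate(gx)

    out._backward = _bw
    return out
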
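"""A compact reverse-mode autodiff engine on numpy arrays.

Only the operations the segmentation pipeline needs are provided: basic
arithmetic with broadcasting, log/clip/relu, reductions, channel softmax,
3x3 convolution (im2col), 2x2 max-pooling, nearest-neighbor upsampling,
channel concatenation, and the channel projection ``x -> M x`` that applies
a grouping matrix to every pixel of a score map.  Everything is float32.
"""

from __future__ import annotations

import numpy as np

from ..errors import DimensionError

__all__ = [
    "Tensor",
    "constant",
    "log",
    "clip",
    "relu",
    "softmax",
    "conv2d",
    "maxpool2d",
    "upsample2d",
    "concat",
    "channel_project",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    return a.astype(np.float32) if a.dtype != np.float32 else a


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray * Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar) node into all parents."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = _as_f32(grad)
        for node in reversed(topo):
            if node._backward is None:
                continue
            gs = node._backward(node.grad)
            for parent, g in zip(node._parents, gs):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=False)
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        out = Tensor(self.data + other.data, _parents=(self, other))
        out._backward = lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        return self + (-other)

    def __rsub__(self, other):
        return constant(other) + (-self)

    def __mul__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        out = Tensor(self.data * other.data, _parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = constant(other) if not isinstance(other, Tensor) else other
        out = Tensor(self.data / other.data, _parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / (other.data**2), other.shape),
        )
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def constant(x) -> Tensor:
    return Tensor(x)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == tuple(shape):
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise

def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _parents=(x,))
    out._backward = lambda g: (g / x.data,)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is passed through inside the range, zero outside."""
    mask = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), _parents=(x,))
    out._backward = lambda g: (g * mask,)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, _parents=(x,))
    out._backward = lambda g: (g * mask,)
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _parents=(x,))

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> contiguous (B, C*k*k, H*W) for stride-1 convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((b, c, k * k, h * w), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            np.copyto(
                cols[:, :, ki * k + kj].reshape(b, c, h, w),
                xp[:, :, ki : ki + h, kj : kj + w],
            )
    return cols.reshape(b, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    b, c, h, w = shape
    cols = cols.reshape(b, c, k * k, h, w)
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + h, kj : kj + w] += cols[:, :, ki * k + kj]
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 same-padding convolution.

    ``weight`` has shape (C_out, C_in, k, k); ``bias`` (C_out,).
    """
    b, c, h, w = x.shape
    co, ci, k, k2 = weight.shape
    if ci != c or k != k2:
        raise DimensionError(f"conv weight {weight.shape} incompatible with input {x.shape}")
    pad = k // 2
    cols = _im2col(x.data, k, pad)  # (B, C*k*k, H*W)
    wmat = weight.data.reshape(co, ci * k * k)
    out_data = np.matmul(wmat, cols)  # (B, C_out, H*W)
    out_data += bias.data[None, :, None]
    out = Tensor(out_data.reshape(b, co, h, w), _parents=(x, weight, bias))

    def bwd(g):
        gm = np.ascontiguousarray(g.reshape(b, co, h * w))
        # batched GEMM against the transposed view avoids tensordot's copies
        dw = np.matmul(gm, cols.swapaxes(1, 2)).sum(axis=0).reshape(weight.shape)
        db = gm.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T, gm)  # (B, C*k*k, H*W)
        dx = _col2im(dcols, x.shape, k, pad)
        return dx, dw, db

    out._backward = bwd
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (H, W must be even)."""
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise DimensionError(f"maxpool2d needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0], _parents=(x,))

    def bwd(g):
        gx = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
        gx = gx.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(b, c, h, w),)

    out._backward = bwd
    return out


def upsample2d(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling."""
    b, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _parents=(x,))

    def bwd(g):
        return (g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)),)

    out._backward = bwd
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _parents=(a, b))
    out._backward = lambda g: (g[:, :ca], g[:, ca:])
    return out


def channel_project(M: np.ndarray, x: Tensor) -> Tensor:
    """Apply a constant matrix to the channel axis of every pixel: ``M @ x``.

    ``M`` is (m, n); ``x`` is (B, n, H, W); the result is (B, m, H, W).
    With ``M = I`` the output is bit-identical to the input (summing exact
    zeros and multiplying by 1.0 are exact in IEEE arithmetic).
    """
    M = np.asarray(M, dtype=np.float32)
    if x.shape[1] != M.shape[1]:
        raise DimensionError(
            f"channel axis has {x.shape[1]} classes but matrix expects {M.shape[1]}"
        )
    out_data = np.tensordot(M, x.data, axes=([1], [1])).transpose(1, 0, 2, 3)
    out = Tensor(np.ascontiguousarray(out_data), _parents=(x,))

    def bwd(g):
        gx = np.tensordot(M.T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
        return (np.ascontiguousarray(gx),)

    out._backward = bwd
    return out
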
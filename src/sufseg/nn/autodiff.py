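"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a 3-D convolutional denoising network on one CPU:
tensors wrap ndarrays, each op records a backward closure, and
``Tensor.backward()`` runs the topologically sorted sweep.  Convolutions use
a 27-offset slice decomposition so every inner product is a BLAS matmul; no
im2col buffers are retained (input windows are recomputed in backward).

float32 is the working dtype for speed; gradient-check tests run the same
graph in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "no_grad",
    "add", "sub", "mul", "div", "neg", "matmul", "tsum", "tmean",
    "reshape", "concat", "sigmoid", "silu", "tlog", "texp", "square", "bce_logits",
    "conv3d", "upsample_nearest", "instance_norm", "dropout", "clip_values",
]

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


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (many layers)
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents and node is not self:
                node.grad = None if not node.requires_grad else node.grad

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other, self.dtype))

    def __sub__(self, other):
        return sub(self, _as_tensor(other, self.dtype))

    def __mul__(self, other):
        return mul(self, _as_tensor(other, self.dtype))

    def __truediv__(self, other):
        return div(self, _as_tensor(other, self.dtype))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, requires_grad={self.requires_grad})"


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def _needs(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _node(data, parents, backward) -> Tensor:
    if _needs(*[p for p in parents if isinstance(p, Tensor)]):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- elementwise arithmetic ---------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(-g, b.shape))

    return _node(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(-g)

    return _node(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    return _node(out_data, (a, b), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(2.0 * a.data * g)

    return _node(a.data**2, (a,), backward)


def tlog(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def texp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _node(out_data, (a,), backward)


def clip_values(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values with a straight-through (identity) gradient.

    Used to keep log() finite in cross-entropy: passing the gradient through
    the clip, combined with the float64 sigmoid backward, reproduces the
    numerically stable logits-space BCE gradient (s - t) even when the
    float32 probabilities round to exactly 0 or 1.
    """

    def backward(g):
        a._accumulate(g)

    return _node(np.clip(a.data, lo, hi), (a,), backward)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed in logit space (stable).

    forward: mean( max(z,0) - z*t + log1p(exp(-|z|)) );
    backward: (sigmoid(z) - t)/n — exact for arbitrarily saturated logits.
    """
    t = np.asarray(target, dtype=z.data.dtype)
    if t.shape != z.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {t.shape}")
    zd = z.data
    val = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    n = zd.size

    def backward(g):
        s = _stable_sigmoid(zd.astype(np.float64))
        z._accumulate((g * (s - t) / n).astype(zd.dtype))

    return _node(val.mean(), (z,), backward)


def sigmoid(a: Tensor) -> Tensor:
    """Logistic squashing; backward in float64 so the derivative never
    underflows to an exact zero while the logits are still recoverable."""
    s64 = _stable_sigmoid(a.data.astype(np.float64))
    s = s64.astype(a.data.dtype)

    def backward(g):
        a._accumulate((g * (s64 * (1.0 - s64))).astype(a.data.dtype))

    return _node(s, (a,), backward)


def silu(a: Tensor) -> Tensor:
    s = _stable_sigmoid(a.data)
    out_data = a.data * s

    def backward(g):
        a._accumulate(g * (s + a.data * s * (1.0 - s)))

    return _node(out_data, (a,), backward)


# -- reductions / shaping -----------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        denom = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        denom = int(np.prod([a.shape[i] for i in ax]))

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.shape) / denom)

    return _node(out_data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(data, tuple(tensors), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _node(out_data, (a, b), backward)


# -- 3-D network primitives ---------------------------------------------

# Reusable scratch buffers: convolution shapes repeat every step, and fresh
# ~50 MB allocations (page faults) would otherwise dominate the gemm time.
_SCRATCH: dict[tuple, np.ndarray] = {}


def _scratch(key: str, shape: tuple, dtype) -> np.ndarray:
    k = (key, shape, np.dtype(dtype).str)
    buf = _SCRATCH.get(k)
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        _SCRATCH[k] = buf
    return buf


def clear_scratch() -> None:
    _SCRATCH.clear()


def _im2col(xp, k, stride, out_shape):
    """Gemm-ready column buffer from a padded (B,C,Dp,Hp,Wp) input.

    Layout: (k^3 * C, B * OD*OH*OW) — one strided copy per kernel offset into
    a contiguous destination, so the whole convolution is a single BLAS gemm.
    The buffer is scratch: valid only until the next _im2col of this shape.
    """
    B, C = xp.shape[:2]
    OD, OH, OW = out_shape
    n = B * OD * OH * OW
    col = _scratch("col", (k**3 * C, n), xp.dtype)
    col5 = col.reshape(k**3, C, B, OD, OH, OW)
    o = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                sl = xp[:, :, dz : dz + OD * stride : stride,
                        dy : dy + OH * stride : stride,
                        dx : dx + OW * stride : stride]
                col5[o] = sl.transpose(1, 0, 2, 3, 4)
                o += 1
    return col


def _pad3(x: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the three spatial axes (faster than np.pad for this case)."""
    if pad == 0:
        return np.ascontiguousarray(x)
    B, C, D, H, W = x.shape
    xp = np.empty((B, C, D + 2 * pad, H + 2 * pad, W + 2 * pad), dtype=x.dtype)
    xp[:, :, :pad, :, :] = 0
    xp[:, :, -pad:, :, :] = 0
    xp[:, :, :, :pad, :] = 0
    xp[:, :, :, -pad:, :] = 0
    xp[:, :, :, :, :pad] = 0
    xp[:, :, :, :, -pad:] = 0
    xp[:, :, pad:-pad, pad:-pad, pad:-pad] = x
    return xp


def _col2im(gcol, xp_shape, k, stride, out_shape, dtype):
    """Scatter-add a column-buffer gradient back onto the padded input."""
    B, C = xp_shape[:2]
    OD, OH, OW = out_shape
    gxp = _scratch("gxp", tuple(xp_shape), dtype)
    gxp.fill(0)
    g5 = gcol.reshape(k**3, C, B, OD, OH, OW)
    o = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                gxp[:, :, dz : dz + OD * stride : stride,
                    dy : dy + OH * stride : stride,
                    dx : dx + OW * stride : stride] += g5[o].transpose(1, 0, 2, 3, 4)
                o += 1
    return gxp


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """3-D convolution, kernel (O, C, k, k, k), zero padding, square stride.

    The column buffer is rebuilt in backward instead of being stored, trading
    a strided copy for ~50 MB of retained memory per full-resolution layer.
    """
    B, C, D, H, W = x.shape
    O, Cw, k = w.shape[0], w.shape[1], w.shape[2]
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C} vs weight {Cw}")
    OD = (D + 2 * pad - k) // stride + 1
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    out_shape = (OD, OH, OW)
    xp = _pad3(x.data, pad)
    col = _im2col(xp, k, stride, out_shape)
    # Weight as (O, k^3*C) matching the column layout (offset-major, then C).
    wcol = np.ascontiguousarray(w.data.transpose(2, 3, 4, 1, 0).reshape(k**3 * C, O).T)
    prod = np.matmul(wcol, col)
    out_data = prod.reshape(O, B, OD, OH, OW).transpose(1, 0, 2, 3, 4)
    out_data = out_data + b.data[None, :, None, None, None]

    def backward(g):
        b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        gf = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(O, -1)
        col_b = _im2col(xp, k, stride, out_shape)  # recomputed, not retained
        gwcol = gf @ col_b.T  # (O, k^3*C)
        w._accumulate(
            gwcol.T.reshape(k, k, k, C, O).transpose(4, 3, 0, 1, 2)
        )
        gcol = _scratch("gcol", (k**3 * C, gf.shape[1]), gf.dtype)
        np.matmul(wcol.T, gf, out=gcol)
        gxp = _col2im(gcol, xp.shape, k, stride, out_shape, g.dtype)
        if pad:
            gx = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
        else:
            gx = gxp
        x._accumulate(gx)

    return _node(out_data, (x, w, b), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the three spatial axes."""
    d = x.data
    for ax in (2, 3, 4):
        d = np.repeat(d, factor, axis=ax)

    def backward(g):
        B, C, D2, H2, W2 = g.shape
        gr = g.reshape(B, C, D2 // factor, factor, H2 // factor, factor, W2 // factor, factor)
        x._accumulate(gr.sum(axis=(3, 5, 7)))

    return _node(d, (x,), backward)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) over its spatial extent."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    n = int(np.prod([x.shape[a] for a in axes]))

    def backward(g):
        gm = g.mean(axis=axes, keepdims=True)
        gym = (g * y).mean(axis=axes, keepdims=True)
        x._accumulate(inv * (g - gm - y * gym))
        _ = n  # spatial size folded into the means above

    return _node(y, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only when stochastic passes are wanted."""
    if not (0 <= rate < 1):
        raise ValueError("dropout rate must lie in [0, 1)")
    if rate == 0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)

    def backward(g):
        x._accumulate(g * keep)

    return _node(x.data * keep, (x,), backward)
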
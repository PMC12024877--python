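"""Parameterized layers for the 3-D denoising network."""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    add,
    conv3d,
    dropout,
    instance_norm,
    matmul,
    reshape,
    silu,
)

__all__ = ["Module", "Linear", "Conv3d", "ResBlock3d", "sinusoidal_embedding"]


class Module:
    """Parameter container; submodules/parameters discovered via __dict__."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0, scale, (n_in, n_out)).astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)


class Conv3d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 1,
        gain: float = 1.0,
        dtype=np.float32,
    ):
        fan_in = c_in * k**3
        scale = gain * np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0, scale, (c_out, c_in, k, k, k)).astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ResBlock3d(Module):
    """Two 3x3x3 convs with instance norm + SiLU; embedding via AdaIN.

    The (time + condition) embedding is projected to a per-channel scale and
    shift applied after the first normalization — adaptive instance
    normalization.  A 1x1x1 projection aligns channels on the skip path.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        emb_dim: int,
        rng: np.random.Generator,
        dropout_rate: float = 0.1,
        dtype=np.float32,
    ):
        self.conv1 = Conv3d(c_in, c_out, rng, dtype=dtype)
        self.conv2 = Conv3d(c_out, c_out, rng, gain=0.5, dtype=dtype)
        self.emb_proj = Linear(emb_dim, 2 * c_out, rng, dtype=dtype)
        self.skip = Conv3d(c_in, c_out, rng, k=1, dtype=dtype) if c_in != c_out else None
        self.dropout_rate = dropout_rate
        self.c_out = c_out

    def __call__(
        self,
        x: Tensor,
        emb: Tensor,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        B = x.shape[0]
        h = instance_norm(self.conv1(x))
        ss = self.emb_proj(emb)  # (B, 2*c_out)
        scale = reshape(ss, (B, 2, self.c_out))
        scale_t = reshape(
            Tensor(np.ones((B, self.c_out), x.dtype)) + _take(scale, 0), (B, self.c_out, 1, 1, 1)
        )
        shift_t = reshape(_take(scale, 1), (B, self.c_out, 1, 1, 1))
        h = h * scale_t + shift_t
        h = silu(h)
        h = instance_norm(self.conv2(h))
        h = silu(h)
        if stochastic and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("stochastic ResBlock pass needs an rng")
            h = dropout(h, self.dropout_rate, rng)
        s = self.skip(x) if self.skip is not None else x
        return h + s


def _take(t: Tensor, idx: int) -> Tensor:
    """Select index ``idx`` on axis 1 of a (B, 2, C) tensor."""
    from .autodiff import _node  # local: tiny structural op

    def backward(g):
        full = np.zeros(t.shape, dtype=g.dtype)
        full[:, idx] = g
        t._accumulate(full)

    return _node(t.data[:, idx], (t,), backward)


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard transformer-style sinusoidal timestep embedding, shape (B, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb
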
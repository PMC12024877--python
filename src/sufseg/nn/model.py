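"""The conditional denoising U-Net: feature encoder + denoising network.

Two parallel encoders with identical level structure process (a) the
conditioning image alone (Feature Encoder, FE) and (b) the channel
concatenation of image and noisy one-hot label x_t (Denoising Network
encoder).  Because the two pyramids match level-for-level, their feature
maps are summed scale-wise; the fused pyramid feeds the decoder through
concatenation skips reduced by 1x1x1 convolutions.  Time and condition
embeddings pass through 2-layer SiLU MLPs and enter every residual block via
adaptive instance normalization.  The network predicts the clean label map
x0-hat directly, squashed per channel to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, sigmoid, upsample_nearest
from .layers import Conv3d, Linear, Module, ResBlock3d, silu, sinusoidal_embedding

__all__ = ["NetConfig", "DenoisingUNet3D", "build_network"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    Full-scale defaults: 4 levels of 3 residual blocks with channels
    64/128/256/512, 256-dim time embedding, 128-dim condition embedding.
    The desk profile shrinks every width; the structure is unchanged.
    """

    levels: int = 4
    blocks_per_level: int = 3
    base_channels: int = 64
    time_embed_dim: int = 256
    cond_embed_dim: int = 128
    in_channels_image: int = 1
    label_channels: int = 2
    cond_features: int = 10  # region one-hot (7) + laterality one-hot (3)
    dropout: float = 0.1

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.time_embed_dim < 8 or self.cond_embed_dim < 8:
            raise ValueError("embedding dimensions must be >= 8")
        if self.label_channels < 2:
            raise ValueError("label_channels must be >= 2 (one-hot)")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.levels))

    @property
    def spatial_divisor(self) -> int:
        return 2 ** (self.levels - 1)


class _Encoder(Module):
    """One pyramid: stem conv, then blocks per level with strided downsamples."""

    def __init__(self, c_in: int, cfg: NetConfig, rng, emb_dim: int):
        ch = cfg.channels
        self.stem = Conv3d(c_in, ch[0], rng)
        self.blocks = [
            [
                ResBlock3d(ch[i], ch[i], emb_dim, rng, cfg.dropout)
                for _ in range(cfg.blocks_per_level)
            ]
            for i in range(cfg.levels)
        ]
        self.downs = [
            Conv3d(ch[i], ch[i + 1], rng, stride=2) for i in range(cfg.levels - 1)
        ]

    def __call__(self, x, emb, stochastic=False, rng=None):
        feats = []
        h = self.stem(x)
        for i, level_blocks in enumerate(self.blocks):
            for blk in level_blocks:
                h = blk(h, emb, stochastic, rng)
            feats.append(h)
            if i < len(self.downs):
                h = self.downs[i](h)
        return feats  # per-level features, shallowest first


class DenoisingUNet3D(Module):
    def __init__(self, cfg: NetConfig, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11E7]))
        self.cfg = cfg
        ch = cfg.channels
        emb = cfg.time_embed_dim

        # Time embedding: sinusoidal -> 2-layer SiLU MLP.
        self.time_mlp1 = Linear(cfg.time_embed_dim, emb, rng)
        self.time_mlp2 = Linear(emb, emb, rng)
        # Condition embedding: descriptor -> cond_embed_dim -> MLP -> emb dim.
        self.cond_in = Linear(cfg.cond_features, cfg.cond_embed_dim, rng)
        self.cond_mlp1 = Linear(cfg.cond_embed_dim, cfg.cond_embed_dim, rng)
        self.cond_mlp2 = Linear(cfg.cond_embed_dim, emb, rng)

        self.fe = _Encoder(cfg.in_channels_image, cfg, rng, emb)
        self.dn = _Encoder(cfg.in_channels_image + cfg.label_channels, cfg, rng, emb)

        top = ch[-1]
        self.bottleneck = [
            ResBlock3d(top, top, emb, rng, cfg.dropout),
            ResBlock3d(top, top, emb, rng, cfg.dropout),
        ]
        self.merge_top = Conv3d(2 * top, top, rng, k=1)

        self.up_convs = []
        self.skip_reduce = []
        self.dec_blocks = []
        for i in reversed(range(cfg.levels - 1)):
            self.up_convs.append(Conv3d(ch[i + 1], ch[i], rng))
            self.skip_reduce.append(Conv3d(2 * ch[i], ch[i], rng, k=1))
            self.dec_blocks.append(
                [
                    ResBlock3d(ch[i], ch[i], emb, rng, cfg.dropout)
                    for _ in range(cfg.blocks_per_level)
                ]
            )
        self.out_conv = Conv3d(ch[0], cfg.label_channels, rng, gain=0.01)

    # ------------------------------------------------------------------
    def embed(self, t, cond: np.ndarray) -> Tensor:
        temb = Tensor(
            sinusoidal_embedding(t, self.cfg.time_embed_dim).astype(np.float32)
        )
        temb = self.time_mlp2(silu(self.time_mlp1(temb)))
        c = Tensor(np.atleast_2d(np.asarray(cond, dtype=np.float32)))
        cemb = self.cond_mlp2(silu(self.cond_mlp1(silu(self.cond_in(c)))))
        return temb + cemb

    def __call__(
        self,
        image: np.ndarray | Tensor,
        xt: np.ndarray | Tensor,
        t,
        cond: np.ndarray,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
        fe_scale: float = 1.0,
        return_logits: bool = False,
    ) -> Tensor:
        """Predict x0-hat, shape (B, N, D, W, H), values in [0, 1].

        ``fe_scale`` scales the feature-encoder contribution (0 disables the
        fusion path — used by ablation checks).  ``stochastic`` activates
        dropout (the MC-dropout uncertainty source).  ``return_logits``
        skips the final squashing — training losses consume logits so BCE
        stays numerically exact.
        """
        img = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
        x = xt if isinstance(xt, Tensor) else Tensor(np.asarray(xt, dtype=np.float32))
        if img.shape[0] != x.shape[0] or img.shape[2:] != x.shape[2:]:
            raise ValueError(
                f"image {img.shape} and xt {x.shape} are not spatially aligned"
            )
        div = self.cfg.spatial_divisor
        if any(s % div for s in img.shape[2:]):
            raise ValueError(
                f"spatial dims {img.shape[2:]} must be divisible by {div} "
                f"(levels={self.cfg.levels})"
            )
        emb = self.embed(t, cond)

        fe_feats = self.fe(img, emb, stochastic, rng)
        dn_in = concat([img, x], axis=1)
        h = self.dn.stem(dn_in)
        fused = []
        for i, level_blocks in enumerate(self.dn.blocks):
            for blk in level_blocks:
                h = blk(h, emb, stochastic, rng)
            f = fe_feats[i]
            if fe_scale != 1.0:
                f = f * Tensor(np.asarray(fe_scale, dtype=np.float32))
            h = h + f  # scale-wise summation of the two pyramids
            fused.append(h)
            if i < len(self.dn.downs):
                h = self.dn.downs[i](h)

        h = fused[-1]
        for blk in self.bottleneck:
            h = blk(h, emb, stochastic, rng)
        h = self.merge_top(concat([h, fused[-1]], axis=1))

        for j, i in enumerate(reversed(range(self.cfg.levels - 1))):
            h = self.up_convs[j](upsample_nearest(h))
            h = self.skip_reduce[j](concat([h, fused[i]], axis=1))
            for blk in self.dec_blocks[j]:
                h = blk(h, emb, stochastic, rng)

        logits = self.out_conv(h)
        return logits if return_logits else sigmoid(logits)

    # -- (de)serialization ---------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise ValueError(f"checkpoint/config mismatch; differing keys: {sorted(missing)[:5]}")
        for k, p in named.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()


def build_network(cfg: NetConfig, seed: int = 0) -> DenoisingUNet3D:
    """Construct the network with seeded, reproducible initialization."""
    return DenoisingUNet3D(cfg, seed=seed)
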
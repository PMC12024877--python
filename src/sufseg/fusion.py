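"""Step-Uncertainty Fusion: combine per-step diffusion predictions.

During DDIM inference every step yields a soft segmentation, and repeated
stochastic passes (fresh initial noise, or MC dropout) yield S predictions
per step.  Two published weighting schemes are provided:

``softmax`` (default)
    Per-voxel variance across the S passes as uncertainty,
    u_t = (1/M) sum_m (p_t^m - pbar_t)^2, turned into per-voxel weights by a
    tempered softmax over the K steps, w_t = exp(-lambda u_t) / sum_k
    exp(-lambda u_k), and the fused map is sum_t w_t * pbar_t.  The tuned
    temperature is lambda = 5.0.

``step-sigmoid``
    Entropy uncertainty u = -pbar ln(pbar) and a step-index prior,
    w_i = exp(sigmoid(i / scale)) * (1 - u): later (more denoised) steps get
    larger weights, uncertain voxels are attenuated.  As written the weights
    are unnormalized; ``normalize=True`` (default in :func:`sufuse`)
    renormalizes per voxel so the fused map stays a probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepPrediction",
    "FusionResult",
    "variance_uncertainty",
    "entropy_uncertainty",
    "softmax_fusion_weights",
    "step_sigmoid_weights",
    "fuse_weighted",
    "sufuse",
]


@dataclass
class StepPrediction:
    """S stochastic soft predictions from one DDIM step.

    ``passes`` has shape (S, ...): soft label maps in [0, 1].
    """

    step_index: int
    passes: np.ndarray

    def __post_init__(self) -> None:
        self.passes = np.asarray(self.passes, dtype=np.float64)
        if self.passes.ndim < 2 or self.passes.shape[0] < 1:
            raise ValueError("passes must have shape (S >= 1, ...)")

    @property
    def n_passes(self) -> int:
        return self.passes.shape[0]

    @property
    def mean_map(self) -> np.ndarray:
        return self.passes.mean(axis=0)


@dataclass
class FusionResult:
    """Fused map plus the per-step diagnostics that produced it."""

    fused: np.ndarray
    weights: np.ndarray  # (K, ...) per-step weight maps
    uncertainty_maps: np.ndarray  # (K, ...) per-step uncertainty
    variant: str
    params: dict = field(default_factory=dict)


def variance_uncertainty(passes: np.ndarray) -> np.ndarray:
    """Per-voxel population variance over the S passes (u >= 0)."""
    passes = np.asarray(passes, dtype=np.float64)
    if passes.ndim < 1 or passes.shape[0] < 1:
        raise ValueError("need at least one pass")
    return passes.var(axis=0, ddof=0)


def entropy_uncertainty(mean_map: np.ndarray) -> np.ndarray:
    """u = -pbar * ln(pbar), with 0*ln(0) = 0; maximal (1/e) at pbar = 1/e."""
    p = np.asarray(mean_map, dtype=np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("mean_map values must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        u = -p * np.log(p)
    return np.where(p > 0, u, 0.0)


def softmax_fusion_weights(u: np.ndarray, lam: float) -> np.ndarray:
    """Per-voxel softmax of -lambda*u across the leading (step) axis."""
    u = np.asarray(u, dtype=np.float64)
    if u.ndim < 1 or u.shape[0] < 1:
        raise ValueError("u must stack K >= 1 step maps on axis 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    z = -lam * u
    z -= z.max(axis=0, keepdims=True)  # stability; softmax is shift-invariant
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def step_sigmoid_weights(step_index: int, scale: float, u: np.ndarray) -> np.ndarray:
    """w = exp(sigmoid(i/scale)) * (1 - u); requires u in [0, 1]."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    u = np.asarray(u, dtype=np.float64)
    if u.min() < -1e-12 or u.max() > 1 + 1e-12:
        raise ValueError("uncertainty must lie in [0, 1] for the (1 - u) factor")
    sig = 1.0 / (1.0 + np.exp(-step_index / scale))
    return np.exp(sig) * (1.0 - np.clip(u, 0.0, 1.0))


def fuse_weighted(means: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-voxel weighted sum over the leading (step) axis."""
    means = np.asarray(means, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if means.shape != weights.shape:
        raise ValueError(f"shape mismatch: means {means.shape} vs weights {weights.shape}")
    return (means * weights).sum(axis=0)


def sufuse(
    trajectory: list[StepPrediction],
    variant: str = "softmax",
    lam: float = 5.0,
    scale: float | None = None,
    normalize: bool = True,
) -> FusionResult:
    """Fuse a K-step trajectory of stochastic predictions into one map.

    Parameters
    ----------
    trajectory
        StepPredictions ordered from least to most denoised (``step_index``
        increasing); K >= 1.
    variant
        ``"softmax"`` (variance uncertainty + tempered softmax, the tuned
        default with lam = 5.0) or ``"step-sigmoid"`` (entropy uncertainty +
        step-index prior).
    scale
        Sigmoid scale for the step prior; defaults to K.
    normalize
        Renormalize weights per voxel to sum to 1 before fusing.  The
        softmax variant is already normalized; for step-sigmoid this makes
        the output a valid probability (the literal unnormalized form is
        ``normalize=False``).
    """
    if len(trajectory) < 1:
        raise ValueError("trajectory must contain at least one StepPrediction")
    shapes = {sp.passes.shape[1:] for sp in trajectory}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent prediction shapes across steps: {shapes}")
    means = np.stack([sp.mean_map for sp in trajectory])

    if variant == "softmax":
        u = np.stack([variance_uncertainty(sp.passes) for sp in trajectory])
        w = softmax_fusion_weights(u, lam)
        params = {"lambda": lam}
    elif variant == "step-sigmoid":
        K = len(trajectory)
        scale = float(K if scale is None else scale)
        u = np.stack([entropy_uncertainty(np.clip(sp.mean_map, 0, 1)) for sp in trajectory])
        # entropy in nats peaks at 1/e < 1, so (1 - u) stays valid as-is
        w = np.stack(
            [
                step_sigmoid_weights(i + 1, scale, u[i])
                for i in range(K)
            ]
        )
        params = {"scale": scale}
    else:
        raise ValueError(f"unknown fusion variant {variant!r}")

    if normalize:
        tot = w.sum(axis=0, keepdims=True)
        w = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 1.0 / len(trajectory))
    fused = fuse_weighted(means, w)
    return FusionResult(fused=fused, weights=w, uncertainty_maps=u, variant=variant, params=params)
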
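"""Forward/reverse diffusion algebra for label maps.

The forward process is the standard variance-preserving Gaussian chain,
x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps, with a linear beta schedule
(0.0001 -> 0.02 over T steps by default).  The network predicts the clean
label map x0-hat directly; the implied noise estimate is recovered
algebraically,

    eps_hat = (x_t - sqrt(abar_t) * x0_hat) / sqrt(1 - abar_t),

and deterministic (eta = 0) DDIM steps jump between arbitrary timesteps:

    x_{t'} = sqrt(abar_{t'}) * x0_hat + sqrt(1 - abar_{t'}) * eps_hat.

Timesteps are 1-based (t = 1..T); abar_0 = 1 is the clean-data sentinel.
Multi-label maps travel through diffusion in one-hot form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "linear_beta_schedule",
    "q_sample",
    "epsilon_from_x0",
    "ddim_step",
    "ddim_timesteps",
    "onehot_encode",
    "onehot_decode",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step noise variances beta_t and cumulative products abar_t."""

    betas: np.ndarray  # shape (T,), betas[i] = beta_{i+1}
    alpha_bars: np.ndarray  # shape (T,), alpha_bars[i] = abar_{i+1}

    @property
    def T(self) -> int:
        return len(self.betas)

    def beta(self, t):
        """beta_t for 1-based t (scalar or array)."""
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"t must lie in [1, {self.T}]")
        return self.betas[t - 1]

    def alpha_bar(self, t):
        """abar_t for 0-based-inclusive t: abar_0 = 1 by convention."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError(f"t must lie in [0, {self.T}]")
        padded = np.concatenate([[1.0], self.alpha_bars])
        return padded[t]


def linear_beta_schedule(
    T: int, beta_start: float = 1e-4, beta_end: float = 0.02
) -> NoiseSchedule:
    """Betas linearly spaced from ``beta_start`` to ``beta_end`` inclusive."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    alpha_bars = np.cumprod(1.0 - betas)
    return NoiseSchedule(betas=betas, alpha_bars=alpha_bars)


def _abar_factors(schedule: NoiseSchedule, t, ndim: int):
    """sqrt(abar_t) and sqrt(1-abar_t), broadcastable over a batch axis."""
    abar = np.asarray(schedule.alpha_bar(t), dtype=np.float64)
    if abar.ndim > 0:  # per-sample t: broadcast over trailing axes
        abar = abar.reshape(abar.shape + (1,) * (ndim - abar.ndim))
    return np.sqrt(abar), np.sqrt(1.0 - abar)


def q_sample(x0: np.ndarray, t, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Forward-noise x0 to timestep t: sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != x0.shape:
        raise ValueError(f"eps shape {eps.shape} does not match x0 shape {x0.shape}")
    t_arr = np.asarray(t)
    if np.any(t_arr < 1) or np.any(t_arr > schedule.T):
        raise ValueError(f"t must lie in [1, {schedule.T}]")
    a, b = _abar_factors(schedule, t, x0.ndim)
    return a * x0 + b * eps


def epsilon_from_x0(
    xt: np.ndarray, x0_hat: np.ndarray, t, schedule: NoiseSchedule
) -> np.ndarray:
    """Noise implied by a clean prediction: (x_t - sqrt(abar) x0hat)/sqrt(1-abar)."""
    xt = np.asarray(xt, dtype=np.float64)
    x0_hat = np.asarray(x0_hat, dtype=np.float64)
    if xt.shape != x0_hat.shape:
        raise ValueError("xt and x0_hat shapes differ")
    abar = np.asarray(schedule.alpha_bar(t), dtype=np.float64)
    if np.any(abar >= 1.0):
        raise ZeroDivisionError(
            "epsilon_from_x0 undefined at abar_t = 1 (t = 0): no noise to recover"
        )
    a, b = _abar_factors(schedule, t, xt.ndim)
    return (xt - a * x0_hat) / b


def ddim_step(
    xt: np.ndarray, x0_hat: np.ndarray, t, t_prev, schedule: NoiseSchedule
) -> np.ndarray:
    """Deterministic DDIM jump from timestep t to t_prev (< t).

    t_prev = 0 returns x0_hat exactly (abar_0 = 1, no residual noise).
    """
    t_a, tp_a = np.asarray(t), np.asarray(t_prev)
    if np.any(tp_a >= t_a):
        raise ValueError(f"t_prev must be < t, got t={t}, t_prev={t_prev}")
    if np.any(tp_a < 0):
        raise ValueError("t_prev must be >= 0")
    eps_hat = epsilon_from_x0(xt, x0_hat, t, schedule)
    a, b = _abar_factors(schedule, t_prev, np.asarray(xt).ndim)
    return a * np.asarray(x0_hat, dtype=np.float64) + b * eps_hat


def ddim_timesteps(T: int, K: int) -> list[int]:
    """K strided timesteps T = t_K > ... > t_1 >= 1 for a K-step trajectory."""
    if not (1 <= K <= T):
        raise ValueError(f"need 1 <= K <= T, got K={K}, T={T}")
    ts = np.unique(np.round(np.linspace(T / K, T, K)).astype(int))
    ts = ts[ts >= 1]
    return list(ts[::-1])


def onehot_encode(labels: np.ndarray, N: int) -> np.ndarray:
    """Integer label map (D, W, H) -> one-hot (N, D, W, H), channel k = label k."""
    labels = np.asarray(labels)
    if N < 2:
        raise ValueError("N must be >= 2 (binary foreground uses N = 2)")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise ValueError("labels must be integer-valued")
        labels = np.round(labels).astype(np.int64)
    if labels.min() < 0 or labels.max() >= N:
        raise ValueError(f"label values must lie in [0, {N - 1}]")
    out = np.zeros((N,) + labels.shape, dtype=np.float32)
    for k in range(N):
        out[k] = labels == k
    return out


def onehot_decode(x: np.ndarray) -> np.ndarray:
    """One-hot / soft label map (N, ...) -> integer map by channel argmax."""
    x = np.asarray(x)
    if x.ndim < 2 or x.shape[0] < 2:
        raise ValueError("expected a multi-channel label map with N >= 2 channels")
    return np.argmax(x, axis=0).astype(np.int64)
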
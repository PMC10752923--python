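"""Distance-decay mixing of latent oscillations into observed channels.

The observed P-channel series is Y(t) = W Z(t) + eps(t): channel p mixes
every latent process within hop distance K of node p in the dependence
graph, with weight decaying in the distance,

    W_pq = decay(d_G(p, q))  if d_G(p, q) <= K,  else 0.

Channels close in the graph share many latents and are strongly coherent;
channels further than 2K apart share none and are independent.  With unit
variance latents the implied covariance of the noiseless signal is W W^T,
which gives closed-form correlations used as exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .ar2 import AR2Spec, simulate_ar2_panel
from .graphs import DependenceGraph, shortest_path_distances

__all__ = [
    "DECAY_FUNCTIONS",
    "MixingModel",
    "MultivariateSeries",
    "mixing_weights",
    "mixing_model",
    "theoretical_correlation",
    "simulate_network_series",
    "noise_sd_for_snr",
]

DECAY_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "inv_linear": lambda x: 1.0 / (1.0 + x),
    "inv_quadratic": lambda x: 1.0 / (1.0 + x**2),
    "exponential": lambda x: np.exp(-x),
}


@dataclass(frozen=True)
class MixingModel:
    """Weight matrix plus the parameters that produced it."""

    W: np.ndarray
    K: int
    decay: str
    noise_sd: float = 0.0


@dataclass(frozen=True)
class MultivariateSeries:
    """T x P observation matrix with its sampling rate."""

    y: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self):
        if self.y.ndim != 2 or self.y.shape[0] < 2 or self.y.shape[1] < 2:
            raise ValueError("series must be a T x P matrix with T >= 2, P >= 2")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("series contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    @property
    def n_channels(self) -> int:
        return self.y.shape[1]


def mixing_weights(d: np.ndarray, K: int, decay: str = "inv_linear") -> np.ndarray:
    """Elementwise decay of the hop-distance matrix, cut off beyond K."""
    if K < 0:
        raise ValueError("K must be >= 0")
    try:
        fn = DECAY_FUNCTIONS[decay]
    except KeyError:
        raise ValueError(
            f"unknown decay {decay!r}; available: {sorted(DECAY_FUNCTIONS)}"
        ) from None
    d = np.asarray(d)
    w = np.where(d <= K, fn(d.astype(float)), 0.0)
    return w


def mixing_model(
    g: DependenceGraph, K: int = 2, decay: str = "inv_linear", noise_sd: float = 0.0
) -> MixingModel:
    """Build the mixing model for a dependence graph."""
    d = shortest_path_distances(g)
    return MixingModel(W=mixing_weights(d, K, decay), K=K, decay=decay, noise_sd=noise_sd)


def theoretical_correlation(W: np.ndarray, noise_sd: float = 0.0) -> np.ndarray:
    """Exact correlation matrix of Y = W Z + eps for unit-variance iid latents.

    Cov Y = W W^T + noise_sd^2 I, so R_pq = (WW^T)_pq / sqrt(V_pp V_qq) for
    p != q with V = WW^T + noise_sd^2 I, and R_pp = 1.
    """
    W = np.asarray(W, dtype=float)
    s = W @ W.T
    v = np.diag(s) + noise_sd**2
    r = s / np.sqrt(np.outer(v, v))
    np.fill_diagonal(r, 1.0)
    return r


def noise_sd_for_snr(W: np.ndarray, target_snr: float) -> float:
    """Noise sd achieving SNR = sigma_S^2 / sigma_N^2 with the signal
    variance averaged over channels: sigma_eps = sqrt(mean diag(WW^T) / SNR)."""
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    W = np.asarray(W, dtype=float)
    sig = float(np.mean(np.einsum("ij,ij->i", W, W)))
    return float(np.sqrt(sig / target_snr))


def simulate_network_series(
    g: DependenceGraph,
    band: AR2Spec,
    K: int = 2,
    decay: str = "inv_linear",
    n_samples: int = 2000,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    burn_in: int = 500,
) -> MultivariateSeries:
    """Simulate Y(t) = W Z(t) + eps(t) on the dependence graph ``g``.

    One latent AR(2) process per node (all sharing the band spec), mixed by
    the distance-decay weights, plus iid Gaussian channel noise.  The root
    seed is split into one stream for the latent panel and one for the noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    latent_ss, noise_ss = ss.spawn(2)
    model = mixing_model(g, K=K, decay=decay, noise_sd=noise_sd)
    panel = simulate_ar2_panel(
        band, n_series=g.n_nodes, n_samples=n_samples, burn_in=burn_in, seed=latent_ss
    )
    y = panel.z @ model.W.T
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(noise_ss).standard_normal(y.shape)
    return MultivariateSeries(y=y, sampling_rate_hz=band.sampling_rate_hz)
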
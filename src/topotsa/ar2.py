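"""Latent band-limited oscillations as AR(2) processes.

Each latent channel is a second-order autoregression

    Z(t) = phi1 Z(t-1) + phi2 Z(t-2) + W(t),   W(t) ~ N(0, sigma^2) iid,

whose characteristic roots are M * exp(+/- i 2 pi f / SR) with modulus
M > 1 (causal/stationary) and phase set by the desired spectral peak
frequency f at sampling rate SR.  This gives

    phi1 = (2 / M) cos(2 pi f / SR),    phi2 = -1 / M^2,

so the spectrum concentrates around f, sharper as M approaches 1.
Simulated panels are standardised to unit *theoretical* stationary
variance, so mixtures of latents have exactly the covariance implied by
the mixing weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "AR2Spec",
    "LatentPanel",
    "BAND_PRESETS",
    "ar2_from_peak",
    "band_preset",
    "ar2_theoretical_spectrum",
    "simulate_ar2_panel",
]

#: Canonical band presets (peak frequency in Hz at SR = 100 Hz).
BAND_PRESETS: dict[str, float] = {
    "delta": 2.0,
    "theta": 5.0,
    "alpha": 10.0,
    "beta": 19.5,
}


@dataclass(frozen=True)
class AR2Spec:
    """Band parameters of one latent oscillation and its AR(2) coefficients."""

    peak_freq_hz: float
    sampling_rate_hz: float
    root_magnitude: float
    innovation_sd: float = 1.0

    def __post_init__(self):
        if not 0 < self.peak_freq_hz < self.sampling_rate_hz / 2:
            raise ValueError(
                f"peak frequency must lie in (0, SR/2) = (0, {self.sampling_rate_hz / 2}); "
                f"got {self.peak_freq_hz}"
            )
        if self.root_magnitude <= 1:
            raise ValueError(
                f"root magnitude must be > 1 for stationarity, got {self.root_magnitude}"
            )
        if self.innovation_sd <= 0:
            raise ValueError("innovation sd must be positive")

    @property
    def psi(self) -> float:
        """Normalised peak frequency f / SR in (0, 0.5)."""
        return self.peak_freq_hz / self.sampling_rate_hz

    @property
    def phi1(self) -> float:
        return (2.0 / self.root_magnitude) * np.cos(2 * np.pi * self.psi)

    @property
    def phi2(self) -> float:
        return -1.0 / self.root_magnitude**2

    @property
    def stationary_variance(self) -> float:
        """Closed-form stationary variance of the AR(2) recursion."""
        p1, p2, s2 = self.phi1, self.phi2, self.innovation_sd**2
        v = s2 * (1 - p2) / ((1 + p2) * ((1 - p2) ** 2 - p1**2))
        if v <= 0:
            raise ValueError("non-stationary AR(2) spec")
        return v


@dataclass(frozen=True)
class LatentPanel:
    """T x P matrix of latent series standardised to unit stationary variance."""

    z: np.ndarray
    spec: AR2Spec

    @property
    def n_series(self) -> int:
        return self.z.shape[1]

    @property
    def n_samples(self) -> int:
        return self.z.shape[0]


def ar2_from_peak(
    peak_freq_hz: float,
    sampling_rate_hz: float,
    root_magnitude: float,
    innovation_sd: float = 1.0,
) -> AR2Spec:
    """Build an AR(2) spec whose spectrum peaks near ``peak_freq_hz``."""
    return AR2Spec(peak_freq_hz, sampling_rate_hz, root_magnitude, innovation_sd)


def band_preset(
    name: str, sampling_rate_hz: float = 100.0, root_magnitude: float = 1.05
) -> AR2Spec:
    """Named band preset (delta/theta/alpha/beta) at the given sampling rate."""
    try:
        f = BAND_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; available: {sorted(BAND_PRESETS)}"
        ) from None
    return ar2_from_peak(f, sampling_rate_hz, root_magnitude)


def ar2_theoretical_spectrum(spec: AR2Spec, freqs_hz: np.ndarray) -> np.ndarray:
    """Spectral density sigma^2 / |1 - phi1 e^{-i 2 pi nu} - phi2 e^{-i 4 pi nu}|^2
    evaluated at the given frequencies (nu = f / SR), normalised so that the
    integral over nu in [0, 1) equals the stationary variance."""
    nu = np.asarray(freqs_hz, dtype=float) / spec.sampling_rate_hz
    z = np.exp(-2j * np.pi * nu)
    denom = np.abs(1.0 - spec.phi1 * z - spec.phi2 * z**2) ** 2
    return spec.innovation_sd**2 / denom


def simulate_ar2_panel(
    spec: AR2Spec,
    n_series: int,
    n_samples: int,
    burn_in: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> LatentPanel:
    """Simulate ``n_series`` independent AR(2) series of length ``n_samples``.

    Each series is driven by Gaussian innovations from its own child stream
    of the root seed (so series i is reproducible regardless of n_series),
    started from zeros with ``burn_in`` discarded samples, and divided by the
    closed-form stationary standard deviation so V Z_p(t) = 1.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_series)
    total = n_samples + burn_in
    w = np.empty((total, n_series))
    for i, child in enumerate(children):
        w[:, i] = np.random.default_rng(child).standard_normal(total)
    w *= spec.innovation_sd
    z = lfilter([1.0], [1.0, -spec.phi1, -spec.phi2], w, axis=0)
    z = z[burn_in:]
    z = z / np.sqrt(spec.stationary_variance)
    return LatentPanel(z=z, spec=spec)
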
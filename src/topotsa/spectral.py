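"""Smoothed-periodogram spectral estimation and coherence distances.

The cross-spectral matrix is estimated by smoothing the periodogram: with
Fourier coefficients d(w_k) = T^{-1/2} sum_t Y(t) exp(-i 2 pi k t / T) the
raw periodogram I(w_k) = d(w_k) d(w_k)^* is an asymptotically unbiased but
inconsistent rank-1 estimate; convolving the matrix sequence with a
non-negative kernel over neighbouring Fourier bins (circularly over the
full grid) gives a consistent, Hermitian positive semidefinite estimate.
Band coherence averages the smoothed matrices over the bins of a frequency
band and forms |f_pq|^2 / (f_pp f_qq) in [0, 1]; a decreasing transform of
coherence is the distance fed to the Vietoris-Rips filtration.

To keep memory linear in T and P, the per-frequency P x P matrices are
never materialised as a dense T x P x P array: the estimate stores the
Fourier coefficients and the kernel, and any smoothed matrix (single bin or
band average) is assembled on demand as a weighted outer-product sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mixing import MultivariateSeries

__all__ = [
    "SpectralEstimate",
    "BandCoherence",
    "CoherenceDistance",
    "periodogram",
    "smooth_periodogram",
    "band_coherence",
    "coherence_distance",
    "default_half_width",
    "kernel_weights",
]


def kernel_weights(kernel: str, half_width: int) -> np.ndarray:
    """Normalised non-negative smoothing kernel on 2*half_width+1 bins."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    n = 2 * half_width + 1
    if kernel == "daniell":
        w = np.ones(n)
    elif kernel == "triangular":
        w = half_width + 1.0 - np.abs(np.arange(n) - half_width)
    elif kernel == "identity":
        w = np.zeros(n)
        w[half_width] = 1.0
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    s = w.sum()
    if s <= 0:
        raise ValueError("kernel weights must sum to a positive value")
    return w / s


def default_half_width(n_samples: int) -> int:
    """Default Daniell half-width, ceil(sqrt(T)/2) bins."""
    return math.ceil(math.sqrt(n_samples) / 2)


@dataclass(frozen=True)
class SpectralEstimate:
    """Cross-spectral estimate at the Fourier grid w_k = k/T (full grid).

    ``coeffs`` holds the T x P Fourier coefficient matrix with the 1/sqrt(T)
    normalisation; ``kernel_id``/``half_width`` describe the smoothing
    applied (``None`` kernel = raw periodogram).
    """

    coeffs: np.ndarray
    sampling_rate_hz: float
    kernel_id: Optional[str] = None
    half_width: int = 0

    @property
    def n_bins(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def freqs_hz(self) -> np.ndarray:
        """Non-negative frequencies of the grid (0 .. SR/2)."""
        t = self.n_bins
        return np.arange(t // 2 + 1) * self.sampling_rate_hz / t

    def _kernel(self) -> Optional[np.ndarray]:
        if self.kernel_id is None:
            return None
        return kernel_weights(self.kernel_id, self.half_width)

    def _bin_weights(self, bins: np.ndarray) -> np.ndarray:
        """Full-grid weights equivalent to (smooth then average over bins)."""
        t = self.n_bins
        w = np.zeros(t)
        kern = self._kernel()
        if kern is None:
            w[bins] = 1.0 / len(bins)
        else:
            h = self.half_width
            for k in bins:
                idx = (np.arange(k - h, k + h + 1)) % t
                w[idx] += kern / len(bins)
        return w

    def matrix(self, k: int) -> np.ndarray:
        """P x P (smoothed) cross-spectral matrix at Fourier bin k."""
        w = self._bin_weights(np.array([k % self.n_bins]))
        return self._weighted_matrix(w)

    def _weighted_matrix(self, w: np.ndarray) -> np.ndarray:
        nz = np.flatnonzero(w)
        d = self.coeffs[nz]
        # entry (p, q) = sum_k w_k d_k[p] conj(d_k[q])
        return (d * w[nz, None]).T @ d.conj()

    def band_matrix(self, band_hz: tuple[float, float]) -> np.ndarray:
        """Average of the smoothed matrices over the Fourier bins in a band."""
        bins = self.band_bins(band_hz)
        return self._weighted_matrix(self._bin_weights(bins))

    def band_bins(self, band_hz: tuple[float, float]) -> np.ndarray:
        lo, hi = band_hz
        if hi < lo:
            raise ValueError("band must satisfy low <= high")
        f = self.freqs_hz
        bins = np.flatnonzero((f >= lo) & (f <= hi))
        if bins.size == 0:
            raise ValueError(
                f"band [{lo}, {hi}] Hz contains no Fourier bin at resolution "
                f"{self.sampling_rate_hz / self.n_bins:.4g} Hz"
            )
        return bins

    def diagonal(self) -> np.ndarray:
        """(T//2+1) x P real matrix of (smoothed) auto-spectra."""
        from scipy.ndimage import convolve1d

        power = np.abs(self.coeffs) ** 2
        kern = self._kernel()
        if kern is not None:
            power = convolve1d(power, kern, axis=0, mode="wrap")
        return power[: self.n_bins // 2 + 1]


@dataclass(frozen=True)
class BandCoherence:
    """P x P coherence matrix for one frequency band."""

    band_hz: tuple[float, float]
    C: np.ndarray


@dataclass(frozen=True)
class CoherenceDistance:
    """P x P distance matrix derived from coherence."""

    D: np.ndarray
    transform_id: str


def periodogram(y: MultivariateSeries) -> SpectralEstimate:
    """Raw periodogram (rank-1 per bin) with channels mean-centred."""
    if y.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if y.n_samples < 8:
        raise ValueError("need at least 8 samples")
    x = y.y - y.y.mean(axis=0, keepdims=True)
    coeffs = np.fft.fft(x, axis=0) / np.sqrt(y.n_samples)
    return SpectralEstimate(coeffs=coeffs, sampling_rate_hz=y.sampling_rate_hz)


def smooth_periodogram(
    raw: SpectralEstimate, kernel: str = "daniell", half_width: Optional[int] = None
) -> SpectralEstimate:
    """Attach a smoothing kernel to the estimate (convolution is applied
    lazily whenever a matrix is materialised)."""
    if half_width is None:
        half_width = default_half_width(raw.n_bins)
    kernel_weights(kernel, half_width)  # validate eagerly
    return SpectralEstimate(
        coeffs=raw.coeffs,
        sampling_rate_hz=raw.sampling_rate_hz,
        kernel_id=kernel,
        half_width=half_width,
    )


def band_coherence(sm: SpectralEstimate, band_hz: tuple[float, float]) -> BandCoherence:
    """Band-averaged coherence |f_pq|^2 / (f_pp f_qq), unit diagonal."""
    f = sm.band_matrix(band_hz)
    p = np.real(np.diag(f)).copy()
    p[p <= 0] = np.finfo(float).tiny
    c = np.abs(f) ** 2 / np.outer(p, p)
    c = np.clip(0.5 * (c + c.T), 0.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return BandCoherence(band_hz=(float(band_hz[0]), float(band_hz[1])), C=c)


_TRANSFORMS = {
    "one_minus": lambda c: 1.0 - c,
    "sqrt_one_minus": lambda c: np.sqrt(1.0 - c),
}


def coherence_distance(
    c: BandCoherence | np.ndarray, transform: str = "one_minus"
) -> CoherenceDistance:
    """Decreasing transform of coherence: distance matrix in [0, 1]."""
    mat = c.C if isinstance(c, BandCoherence) else np.asarray(c, dtype=float)
    if mat.min() < -1e-9 or mat.max() > 1 + 1e-9:
        raise ValueError("coherence entries must lie in [0, 1]")
    try:
        fn = _TRANSFORMS[transform]
    except KeyError:
        raise ValueError(
            f"unknown transform {transform!r}; available: {sorted(_TRANSFORMS)}"
        ) from None
    d = fn(np.clip(mat, 0.0, 1.0))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return CoherenceDistance(D=d, transform_id=transform)
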
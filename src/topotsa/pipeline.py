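"""End-to-end analysis pipeline: series -> coherence distance -> diagram.

Convenience wrappers that chain the spectral and persistence stages with
the package defaults (Daniell kernel of half-width ceil(sqrt(T)/2) bins,
mid frequency band 8-12 Hz, distance transform 1 - coherence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ar2 import AR2Spec
from .graphs import DependenceGraph
from .mixing import MultivariateSeries, simulate_network_series
from .persistence import PersistenceDiagram, vr_persistence
from .spectral import (
    band_coherence,
    coherence_distance,
    default_half_width,
    periodogram,
    smooth_periodogram,
)

__all__ = ["SpectralOptions", "MID_BAND", "HIGH_BAND", "coherence_distance_matrix",
           "analyze_series", "simulate_and_analyze"]

#: Default analysis bands at SR = 100 Hz.
MID_BAND: tuple[float, float] = (8.0, 12.0)
HIGH_BAND: tuple[float, float] = (30.0, 50.0)


@dataclass(frozen=True)
class SpectralOptions:
    """Estimation choices for the coherence-distance stage."""

    kernel: str = "daniell"
    half_width: Optional[int] = None  # None -> ceil(sqrt(T)/2)
    band_hz: tuple[float, float] = MID_BAND
    transform: str = "one_minus"


def coherence_distance_matrix(
    y: MultivariateSeries, options: SpectralOptions = SpectralOptions()
) -> np.ndarray:
    """Smoothed-periodogram band coherence turned into a distance matrix."""
    raw = periodogram(y)
    hw = options.half_width
    if hw is None:
        hw = default_half_width(y.n_samples)
    sm = smooth_periodogram(raw, kernel=options.kernel, half_width=hw)
    c = band_coherence(sm, options.band_hz)
    return coherence_distance(c, transform=options.transform).D


def analyze_series(
    y: MultivariateSeries,
    options: SpectralOptions = SpectralOptions(),
    max_dim: int = 1,
) -> PersistenceDiagram:
    """Full analysis half of the pipeline on an observed series."""
    return vr_persistence(coherence_distance_matrix(y, options), max_dim=max_dim)


def simulate_and_analyze(
    g: DependenceGraph,
    band: AR2Spec,
    K: int = 2,
    decay: str = "inv_linear",
    n_samples: int = 2000,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    options: SpectralOptions = SpectralOptions(),
    max_dim: int = 1,
) -> PersistenceDiagram:
    """Simulate a network series on ``g`` and recover its persistence diagram."""
    y = simulate_network_series(
        g, band, K=K, decay=decay, n_samples=n_samples, noise_sd=noise_sd, seed=seed
    )
    return analyze_series(y, options=options, max_dim=max_dim)
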
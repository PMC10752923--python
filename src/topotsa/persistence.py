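"""Vietoris-Rips persistence diagrams, total persistence, feature counts.

The filtration is built over a finite metric space given as a symmetric
zero-diagonal distance matrix: a simplex enters at the maximum pairwise
distance of its vertices.  Homology is computed with Z/2 coefficients by
the reduction kernels in :mod:`topotsa._reduction`.

By default the filtration is truncated at the enclosing radius
min_p max_q D[p, q]; beyond it the complex is a cone, so every feature of
positive dimension has already died and the diagram equals that of the full
filtration (with exactly one essential 0-dimensional class).  A smaller
explicit ``thresh`` may be passed, in which case features still alive at
the threshold are reported with death = +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._reduction import binom_table, reduce_dim0, reduce_dim1, reduce_dim2
from .spectral import CoherenceDistance

__all__ = [
    "PersistenceDiagram",
    "vr_persistence",
    "total_persistence",
    "prominent_features",
]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (dimension, birth, death) features; death may be +inf."""

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray

    def __post_init__(self):
        if not (len(self.dims) == len(self.births) == len(self.deaths)):
            raise ValueError("dims, births, deaths must have equal length")
        if np.any(self.deaths < self.births):
            raise ValueError("every death must be >= its birth")

    def __len__(self) -> int:
        return len(self.dims)

    def features(self, k: int | None = None) -> np.ndarray:
        """(m, 3) array of [dim, birth, death] rows, optionally one dimension."""
        out = np.column_stack([self.dims.astype(float), self.births, self.deaths])
        if k is not None:
            out = out[self.dims == k]
        return out

    def lifetimes(self, k: int) -> np.ndarray:
        sel = self.dims == k
        return self.deaths[sel] - self.births[sel]

    def concat(self, other: "PersistenceDiagram") -> "PersistenceDiagram":
        return PersistenceDiagram(
            dims=np.concatenate([self.dims, other.dims]),
            births=np.concatenate([self.births, other.births]),
            deaths=np.concatenate([self.deaths, other.deaths]),
        )


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if D.min() < 0:
        raise ValueError("distances must be non-negative")
    return 0.5 * (D + D.T)


def vr_persistence(
    D: CoherenceDistance | np.ndarray,
    max_dim: int = 1,
    thresh: float | None = None,
) -> PersistenceDiagram:
    """Vietoris-Rips persistent homology of a finite metric space.

    Parameters
    ----------
    D : square symmetric matrix (or CoherenceDistance) with zero diagonal.
    max_dim : largest homology dimension to compute (1 or 2).
    thresh : optional filtration cutoff; default is the enclosing radius,
        which yields the exact full-filtration diagram.
    """
    if isinstance(D, CoherenceDistance):
        D = D.D
    D = _validate_distance_matrix(D)
    if max_dim not in (1, 2):
        raise ValueError("max_dim must be 1 or 2")
    p = D.shape[0]

    if p == 1:
        return PersistenceDiagram(
            dims=np.array([0]), births=np.array([0.0]), deaths=np.array([np.inf])
        )

    levels, inverse = np.unique(D, return_inverse=True)
    didx = inverse.reshape(D.shape).astype(np.int64)

    enclosing = float(np.min(np.max(D, axis=1)))
    thresh_eff = enclosing if thresh is None else min(float(thresh), enclosing)
    thresh_idx = int(np.searchsorted(levels, thresh_eff, side="right") - 1)

    binom = binom_table(p)
    kmax = 4 if max_dim == 2 else 3
    n_top = max(int(binom[p, k]) for k in range(2, kmax + 1))
    shift = max(n_top.bit_length(), 1)
    if (int(levels.size) << shift) >= 2**62:
        raise ValueError("problem too large for the int64 key encoding")

    dims: list[int] = []
    births: list[float] = []
    deaths: list[float] = []

    d0_deaths, merge_ranks, n_comp = reduce_dim0(didx, thresh_idx)
    for lv in d0_deaths:
        if levels[lv] > 0:
            dims.append(0)
            births.append(0.0)
            deaths.append(float(levels[lv]))
    for _ in range(n_comp):
        dims.append(0)
        births.append(0.0)
        deaths.append(np.inf)

    cleared_edges = np.zeros(p * (p - 1) // 2, dtype=np.bool_)
    cleared_edges[merge_ranks] = True

    b1, d1, piv1 = reduce_dim1(didx, thresh_idx, cleared_edges, binom, shift)
    for b, d in zip(b1, d1):
        if d < 0:
            dims.append(1)
            births.append(float(levels[b]))
            deaths.append(np.inf)
        elif d > b:
            dims.append(1)
            births.append(float(levels[b]))
            deaths.append(float(levels[d]))

    if max_dim == 2:
        cleared_tris = np.zeros(int(binom[p, 3]), dtype=np.bool_)
        cleared_tris[piv1[piv1 >= 0]] = True
        b2, d2, _ = reduce_dim2(didx, thresh_idx, cleared_tris, binom, shift)
        for b, d in zip(b2, d2):
            if d < 0:
                dims.append(2)
                births.append(float(levels[b]))
                deaths.append(np.inf)
            elif d > b:
                dims.append(2)
                births.append(float(levels[b]))
                deaths.append(float(levels[d]))

    return PersistenceDiagram(
        dims=np.asarray(dims, dtype=int),
        births=np.asarray(births, dtype=float),
        deaths=np.asarray(deaths, dtype=float),
    )


def total_persistence(
    pd: PersistenceDiagram, k: int, truncate_at: float | None = None
) -> float:
    """Sum of lifetimes (death - birth) of the dimension-k features.

    Features with infinite death (the essential connected component, or
    classes surviving an explicit threshold) are excluded unless
    ``truncate_at`` is given, in which case their death is clipped there.
    """
    life = pd.lifetimes(k)
    if truncate_at is not None:
        sel = pd.dims == k
        life = np.minimum(pd.deaths[sel], truncate_at) - pd.births[sel]
        life = np.maximum(life, 0.0)
        return float(life.sum())
    return float(life[np.isfinite(life)].sum())


def prominent_features(
    pd: PersistenceDiagram, k: int, rel_threshold: float = 0.5
) -> int:
    """Number of dimension-k features with lifetime >= rel_threshold times
    the maximum dimension-k lifetime (empirical Betti count).

    Infinite-lifetime features are always counted; the reference maximum is
    taken over the finite lifetimes.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    life = pd.lifetimes(k)
    if life.size == 0:
        return 0
    n_inf = int(np.sum(np.isinf(life)))
    finite = life[np.isfinite(life)]
    if finite.size == 0 or finite.max() <= 0:
        return n_inf
    return n_inf + int(np.sum(finite >= rel_threshold * finite.max()))
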
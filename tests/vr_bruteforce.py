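"""Brute-force Vietoris-Rips persistence oracle for small point sets.

Enumerates every simplex up to dimension max_dim+1, sorts them into a
simplexwise filtration (diameter, then dimension, then lexicographic), and
reduces the full boundary matrix over Z/2 with plain Python sets.  Runs in
exponential time; intended for n <= 8 points.  Kept deliberately
independent of the package's reduction kernels.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["vr_bruteforce"]


def vr_bruteforce(D, max_dim: int = 1):
    """Return sorted [(dim, birth, death)] features; death may be inf.

    Zero-persistence pairs are dropped, matching the convention of the
    package's diagrams.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    simplices = []
    for d in range(max_dim + 2):
        for s in itertools.combinations(range(n), d + 1):
            diam = max((D[a, b] for a, b in itertools.combinations(s, 2)), default=0.0)
            simplices.append((diam, d, s))
    simplices.sort(key=lambda x: (x[0], x[1], x[2]))
    index = {s: i for i, (_, _, s) in enumerate(simplices)}

    columns = []
    for _, d, s in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append({index[f] for f in itertools.combinations(s, d)})

    pivot_owner: dict[int, int] = {}
    pairs = []
    for j, col in enumerate(columns):
        while col:
            piv = max(col)
            if piv in pivot_owner:
                col ^= columns[pivot_owner[piv]]
            else:
                pivot_owner[piv] = j
                pairs.append((piv, j))
                break

    paired = set()
    features = []
    for piv, j in pairs:
        paired.add(piv)
        paired.add(j)
        birth, death = simplices[piv][0], simplices[j][0]
        if death > birth:
            features.append((simplices[piv][1], birth, death))
    for i, (diam, d, _) in enumerate(simplices):
        if i not in paired and d <= max_dim:
            features.append((d, diam, np.inf))
    return sorted(features)
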
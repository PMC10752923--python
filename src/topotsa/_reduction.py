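"""Low-level Vietoris-Rips persistence kernels.

Persistence pairs are computed one dimension at a time by left-to-right
column reduction of the anti-transposed coboundary matrix (the cohomology
ordering), with clearing between dimensions:

* dimension 0 by Kruskal union-find over the edges;
* dimension d >= 1 by reducing columns indexed by d-simplices in decreasing
  filtration order, whose entries are their (d+1)-dimensional cofacets; the
  pivot is the cofacet minimal in filtration order.  d-simplices that were
  pivots (deaths) one dimension below are skipped (clearing).

Distances are quantised to integer levels (indices into the sorted unique
distance values), so all filtration comparisons are exact, and a simplex is
encoded as a single int64 key ``(diameter_level << shift) | colex_rank``
whose natural order is the filtration order.  Reduced columns are stored in
factored form — the list of column simplices accumulated — and their
coboundaries are re-enumerated on demand, keeping memory proportional to
the number of pivots rather than the number of (d+1)-simplices (for P=153
and dimension 2 there are ~2.2e7 tetrahedra; they are never enumerated).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.core import types
from numba.typed import Dict

__all__ = ["binom_table", "reduce_dim0", "reduce_dim1", "reduce_dim2"]


def binom_table(n: int, kmax: int = 5) -> np.ndarray:
    b = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    b[:, 0] = 1
    for i in range(1, n + 1):
        for k in range(1, kmax + 1):
            b[i, k] = b[i - 1, k - 1] + b[i - 1, k]
    return b


def reduce_dim0(didx: np.ndarray, thresh_idx: int):
    """Union-find over edges in filtration order.

    Returns (death_levels, merge_edge_ranks, n_components).
    """
    p = didx.shape[0]
    iu, ju = np.triu_indices(p, 1)
    lev = didx[iu, ju]
    keep = lev <= thresh_idx
    iu, ju, lev = iu[keep], ju[keep], lev[keep]
    rank = ju * (ju - 1) // 2 + iu
    order = np.lexsort((rank, lev))

    parent = np.arange(p)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    deaths = []
    merge_ranks = []
    n_comp = p
    for t in order:
        a, b = find(int(iu[t])), find(int(ju[t]))
        if a != b:
            parent[a] = b
            deaths.append(int(lev[t]))
            merge_ranks.append(int(rank[t]))
            n_comp -= 1
            if n_comp == 1:
                break
    return (
        np.asarray(deaths, dtype=np.int64),
        np.asarray(merge_ranks, dtype=np.int64),
        n_comp,
    )


@njit(cache=False)
def _cancel(buf, nbuf):
    """Sort buf[:nbuf] and keep one representative of each odd-parity run."""
    if nbuf == 0:
        return 0
    buf[:nbuf].sort()
    m = 0
    i = 0
    while i < nbuf:
        j = i + 1
        while j < nbuf and buf[j] == buf[i]:
            j += 1
        if (j - i) & 1:
            buf[m] = buf[i]
            m += 1
        i = j
    return m


@njit(cache=False)
def _grow(buf, need):
    if need <= buf.size:
        return buf
    cap = buf.size
    while cap < need:
        cap *= 2
    out = np.empty(cap, buf.dtype)
    out[: buf.size] = buf
    return out


@njit(cache=False)
def _edge_cofacets(buf, nbuf, i, j, didx, thresh_idx, binom, shift):
    """Append keys of triangles containing edge (i < j) to buf[:nbuf]."""
    p = didx.shape[0]
    de = didx[i, j]
    for v in range(p):
        if v == i or v == j:
            continue
        dt = de
        if didx[v, i] > dt:
            dt = didx[v, i]
        if didx[v, j] > dt:
            dt = didx[v, j]
        if dt > thresh_idx:
            continue
        if v < i:
            r = binom[j, 3] + binom[i, 2] + v
        elif v < j:
            r = binom[j, 3] + binom[v, 2] + i
        else:
            r = binom[v, 3] + binom[j, 2] + i
        buf[nbuf] = (dt << shift) | r
        nbuf += 1
    return nbuf


@njit(cache=False)
def _tri_cofacets(buf, nbuf, i, j, k, didx, thresh_idx, binom, shift):
    """Append keys of tetrahedra containing triangle (i < j < k)."""
    p = didx.shape[0]
    dt0 = didx[i, j]
    if didx[i, k] > dt0:
        dt0 = didx[i, k]
    if didx[j, k] > dt0:
        dt0 = didx[j, k]
    for v in range(p):
        if v == i or v == j or v == k:
            continue
        dt = dt0
        if didx[v, i] > dt:
            dt = didx[v, i]
        if didx[v, j] > dt:
            dt = didx[v, j]
        if didx[v, k] > dt:
            dt = didx[v, k]
        if dt > thresh_idx:
            continue
        if v < i:
            r = binom[k, 4] + binom[j, 3] + binom[i, 2] + v
        elif v < j:
            r = binom[k, 4] + binom[j, 3] + binom[v, 2] + i
        elif v < k:
            r = binom[k, 4] + binom[v, 3] + binom[j, 2] + i
        else:
            r = binom[v, 4] + binom[k, 3] + binom[j, 2] + i
        buf[nbuf] = (dt << shift) | r
        nbuf += 1
    return nbuf


@njit(cache=False)
def reduce_dim1(didx, thresh_idx, cleared_edges, binom, shift):
    """Reduce the edge/triangle coboundary; see module docstring.

    Returns (birth_levels, death_levels, pivot_tri_ranks, essential flag via
    death level == -1).
    """
    p = didx.shape[0]
    # assemble edge columns (skip cleared = dim-0 merge edges)
    n_max = (p * (p - 1)) // 2
    keys = np.empty(n_max, np.int64)
    va = np.empty(n_max, np.int16)
    vb = np.empty(n_max, np.int16)
    n = 0
    for i in range(p):
        for j in range(i + 1, p):
            d = didx[i, j]
            if d > thresh_idx:
                continue
            r = j * (j - 1) // 2 + i
            if cleared_edges[r]:
                continue
            keys[n] = (np.int64(d) << shift) | r
            va[n] = i
            vb[n] = j
            n += 1
    order = np.argsort(keys[:n])

    owner = Dict.empty(types.int64, types.int64)
    vpool = np.empty(max(4 * n, 16), np.int64)  # packed (i | j<<16) edge verts
    voff = np.empty(n + 1, np.int64)
    voff[0] = 0
    n_stored = 0

    births = np.empty(n, np.int64)
    deaths = np.empty(n, np.int64)
    pivot_ranks = np.empty(n, np.int64)
    n_out = 0

    buf = np.empty(4096, np.int64)
    vcur = np.empty(256, np.int64)

    for t in range(n - 1, -1, -1):
        idx = order[t]
        ci, cj = int(va[idx]), int(vb[idx])
        cdiam = keys[idx] >> shift
        # emergent-pair shortcut: enumerating cofacets in ascending vertex
        # order gives ascending colex ranks, so the first cofacet with the
        # same diameter as the column is the pivot of the unreduced column;
        # if it is unclaimed the column is already reduced.
        de = didx[ci, cj]
        emergent = np.int64(-1)
        for v in range(p):
            if v == ci or v == cj:
                continue
            dt = de
            if didx[v, ci] > dt:
                dt = didx[v, ci]
            if didx[v, cj] > dt:
                dt = didx[v, cj]
            if dt != cdiam:
                continue
            if v < ci:
                r = binom[cj, 3] + binom[ci, 2] + v
            elif v < cj:
                r = binom[cj, 3] + binom[v, 2] + ci
            else:
                r = binom[v, 3] + binom[cj, 2] + ci
            emergent = (dt << shift) | r
            break
        if emergent >= 0 and emergent not in owner:
            owner[emergent] = n_stored
            end = voff[n_stored] + 1
            vpool = _grow(vpool, end)
            vpool[voff[n_stored]] = ci | (cj << 16)
            voff[n_stored + 1] = end
            n_stored += 1
            births[n_out] = cdiam
            deaths[n_out] = cdiam
            pivot_ranks[n_out] = emergent & ((np.int64(1) << shift) - 1)
            n_out += 1
            continue
        buf = _grow(buf, p)
        nbuf = _edge_cofacets(buf, 0, ci, cj, didx, thresh_idx, binom, shift)
        nv = 1
        vcur[0] = ci | (cj << 16)
        while True:
            nbuf = _cancel(buf, nbuf)
            if nbuf == 0:
                births[n_out] = keys[idx] >> shift
                deaths[n_out] = -1
                pivot_ranks[n_out] = -1
                n_out += 1
                break
            piv = buf[0]
            if piv in owner:
                cid = owner[piv]
                s, e = voff[cid], voff[cid + 1]
                buf = _grow(buf, nbuf + (e - s) * p)
                if nv + (e - s) > vcur.size:
                    vcur = _grow(vcur, nv + (e - s))
                for u in range(s, e):
                    pk = vpool[u]
                    oi = int(pk & 0xFFFF)
                    oj = int(pk >> 16)
                    nbuf = _edge_cofacets(
                        buf, nbuf, oi, oj, didx, thresh_idx, binom, shift
                    )
                    vcur[nv] = pk
                    nv += 1
            else:
                owner[piv] = n_stored
                end = voff[n_stored] + nv
                vpool = _grow(vpool, end)
                vpool[voff[n_stored] : end] = vcur[:nv]
                voff[n_stored + 1] = end
                n_stored += 1
                births[n_out] = keys[idx] >> shift
                deaths[n_out] = piv >> shift
                pivot_ranks[n_out] = piv & ((np.int64(1) << shift) - 1)
                n_out += 1
                break
    return births[:n_out], deaths[:n_out], pivot_ranks[:n_out]


@njit(cache=False)
def reduce_dim2(didx, thresh_idx, cleared_tris, binom, shift):
    """Reduce the triangle/tetrahedron coboundary; see module docstring."""
    p = didx.shape[0]
    n_max = binom[p, 3]
    keys = np.empty(n_max, np.int64)
    va = np.empty(n_max, np.int16)
    vb = np.empty(n_max, np.int16)
    vc = np.empty(n_max, np.int16)
    n = 0
    for i in range(p):
        for j in range(i + 1, p):
            dij = didx[i, j]
            if dij > thresh_idx:
                continue
            bj = binom[j, 2] + i
            for k in range(j + 1, p):
                dt = dij
                if didx[i, k] > dt:
                    dt = didx[i, k]
                if didx[j, k] > dt:
                    dt = didx[j, k]
                if dt > thresh_idx:
                    continue
                r = binom[k, 3] + bj
                if cleared_tris[r]:
                    continue
                keys[n] = (np.int64(dt) << shift) | r
                va[n] = i
                vb[n] = j
                vc[n] = k
                n += 1
    order = np.argsort(keys[:n])

    owner = Dict.empty(types.int64, types.int64)
    vpool = np.empty(max(4 * n, 16), np.int64)  # packed (i | j<<16 | k<<32)
    voff = np.empty(n + 1, np.int64)
    voff[0] = 0
    n_stored = 0

    births = np.empty(n, np.int64)
    deaths = np.empty(n, np.int64)
    pivot_ranks = np.empty(n, np.int64)
    n_out = 0

    buf = np.empty(4096, np.int64)
    vcur = np.empty(256, np.int64)

    for t in range(n - 1, -1, -1):
        idx = order[t]
        ci, cj, ck = int(va[idx]), int(vb[idx]), int(vc[idx])
        cdiam = keys[idx] >> shift
        # emergent-pair shortcut (see reduce_dim1)
        dt0 = didx[ci, cj]
        if didx[ci, ck] > dt0:
            dt0 = didx[ci, ck]
        if didx[cj, ck] > dt0:
            dt0 = didx[cj, ck]
        emergent = np.int64(-1)
        for v in range(p):
            if v == ci or v == cj or v == ck:
                continue
            dt = dt0
            if didx[v, ci] > dt:
                dt = didx[v, ci]
            if didx[v, cj] > dt:
                dt = didx[v, cj]
            if didx[v, ck] > dt:
                dt = didx[v, ck]
            if dt != cdiam:
                continue
            if v < ci:
                r = binom[ck, 4] + binom[cj, 3] + binom[ci, 2] + v
            elif v < cj:
                r = binom[ck, 4] + binom[cj, 3] + binom[v, 2] + ci
            elif v < ck:
                r = binom[ck, 4] + binom[v, 3] + binom[cj, 2] + ci
            else:
                r = binom[v, 4] + binom[ck, 3] + binom[cj, 2] + ci
            emergent = (dt << shift) | r
            break
        if emergent >= 0 and emergent not in owner:
            owner[emergent] = n_stored
            end = voff[n_stored] + 1
            vpool = _grow(vpool, end)
            vpool[voff[n_stored]] = ci | (cj << 16) | (np.int64(ck) << 32)
            voff[n_stored + 1] = end
            n_stored += 1
            births[n_out] = cdiam
            deaths[n_out] = cdiam
            pivot_ranks[n_out] = emergent & ((np.int64(1) << shift) - 1)
            n_out += 1
            continue
        buf = _grow(buf, p)
        nbuf = _tri_cofacets(buf, 0, ci, cj, ck, didx, thresh_idx, binom, shift)
        nv = 1
        vcur[0] = ci | (cj << 16) | (np.int64(ck) << 32)
        while True:
            nbuf = _cancel(buf, nbuf)
            if nbuf == 0:
                births[n_out] = keys[idx] >> shift
                deaths[n_out] = -1
                pivot_ranks[n_out] = -1
                n_out += 1
                break
            piv = buf[0]
            if piv in owner:
                cid = owner[piv]
                s, e = voff[cid], voff[cid + 1]
                buf = _grow(buf, nbuf + (e - s) * p)
                if nv + (e - s) > vcur.size:
                    vcur = _grow(vcur, nv + (e - s))
                for u in range(s, e):
                    pk = vpool[u]
                    oi = int(pk & 0xFFFF)
                    oj = int((pk >> 16) & 0xFFFF)
                    ok = int(pk >> 32)
                    nbuf = _tri_cofacets(
                        buf, nbuf, oi, oj, ok, didx, thresh_idx, binom, shift
                    )
                    vcur[nv] = pk
                    nv += 1
            else:
                owner[piv] = n_stored
                end = voff[n_stored] + nv
                vpool = _grow(vpool, end)
                vpool[voff[n_stored] : end] = vcur[:nv]
                voff[n_stored + 1] = end
                n_stored += 1
                births[n_out] = keys[idx] >> shift
                deaths[n_out] = piv >> shift
                pivot_ranks[n_out] = piv & ((np.int64(1) << shift) - 1)
                n_out += 1
                break
    return births[:n_out], deaths[:n_out], pivot_ranks[:n_out]
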
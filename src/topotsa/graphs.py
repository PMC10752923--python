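"""Ground-truth dependence graphs and their hop-count metrics.

The dependence network of the simulated multivariate series is prescribed by
a graph: nodes are channels, edges are direct dependencies, and the mixing
weights decay with the hop-count (shortest-path) distance.  This module
provides the canonical constructors used throughout the package — circular
ladders (one essential cycle), double circular ladders (two main cycles),
periodic grids (torus) and the dodecahedral graph (sphere) — plus a generic
sampler that builds a graph from a flat polygon with identified edges via a
periodic Voronoi tessellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import Voronoi

__all__ = [
    "DependenceGraph",
    "PolygonQuotientSpec",
    "UNREACHABLE",
    "circular_ladder",
    "double_circular_ladder",
    "torus_grid",
    "dodecahedron",
    "sample_quotient_graph",
    "shortest_path_distances",
]

#: Sentinel hop count for unreachable node pairs (large enough to exceed any
#: cutoff K while keeping the matrix integer-valued).
UNREACHABLE = 2**30


@dataclass(frozen=True)
class DependenceGraph:
    """An undirected simple graph on nodes ``0 .. n_nodes-1``.

    Node indices are zero-based internally; the edge-list text format is
    one-based (see :mod:`topotsa.io`).
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("graph needs at least one node")
        seen = set()
        norm = []
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range for P={self.n_nodes}")
            e = (min(i, j), max(i, j))
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
            norm.append(e)
        object.__setattr__(self, "edges", tuple(sorted(norm)))
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels must match n_nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


@dataclass(frozen=True)
class PolygonQuotientSpec:
    """A flat rectangle with optionally identified opposite edges.

    Wrapping both axes yields a torus, one axis a cylinder.  Setting an
    ``reverse_*`` flag glues the corresponding pair of edges with reversed
    orientation (non-orientable identifications; provided for completeness,
    only the torus and cylinder are tested constructions).
    """

    rows: int
    cols: int
    wrap_rows: bool = True
    wrap_cols: bool = True
    reverse_rows: bool = False
    reverse_cols: bool = False

    def __post_init__(self):
        if self.wrap_rows and self.rows < 3:
            raise ValueError("rows >= 3 required when the row axis wraps")
        if self.wrap_cols and self.cols < 3:
            raise ValueError("cols >= 3 required when the column axis wraps")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")


def _graph_from_edges(n: int, edges: Iterable[tuple[int, int]]) -> DependenceGraph:
    return DependenceGraph(n_nodes=n, edges=tuple(edges))


def circular_ladder(n_rungs: int) -> DependenceGraph:
    """Circular-ladder graph: two concentric ``n_rungs``-cycles joined by rungs.

    Nodes ``0 .. n_rungs-1`` form the inner cycle (consecutively adjacent,
    wrapped), ``n_rungs .. 2*n_rungs-1`` the outer cycle, with rung edges
    ``i — i+n_rungs``.  The graph is 3-regular with one essential cycle at
    the homotopy level.
    """
    if n_rungs < 3:
        raise ValueError(f"n_rungs must be >= 3, got {n_rungs}")
    n = n_rungs
    edges = []
    for i in range(n):
        edges.append((i, (i + 1) % n))            # inner cycle
        edges.append((n + i, n + (i + 1) % n))    # outer cycle
        edges.append((i, n + i))                  # rung
    return _graph_from_edges(2 * n, edges)


def double_circular_ladder(n_rungs_per_lobe: int, n_bridges: int = 2) -> DependenceGraph:
    """Two circular ladders ("lobes") joined by bridge edges.

    The default ``n_bridges=2`` joins the lobes by one rung-aligned pair of
    edges (inner–inner and outer–outer at rung 0 of each lobe), so the
    dependence network has exactly two main cycles (a figure-eight after
    contracting the bridge rung).  ``n_bridges=1`` uses a single inner
    bridge (a plain wedge of the two lobes).
    """
    if n_rungs_per_lobe < 3:
        raise ValueError(f"n_rungs_per_lobe must be >= 3, got {n_rungs_per_lobe}")
    if n_bridges not in (1, 2):
        raise ValueError("n_bridges must be 1 or 2")
    m = n_rungs_per_lobe
    lobe = circular_ladder(m)
    off = 2 * m
    edges = list(lobe.edges) + [(i + off, j + off) for i, j in lobe.edges]
    edges.append((0, off))            # inner-inner bridge
    if n_bridges == 2:
        edges.append((m, off + m))    # outer-outer bridge, rung-aligned
    return _graph_from_edges(4 * m, edges)


def torus_grid(rows: int, cols: int) -> DependenceGraph:
    """``rows x cols`` lattice with both axes periodic (4-neighbour torus)."""
    if rows < 3 or cols < 3:
        raise ValueError(f"rows and cols must be >= 3, got ({rows},{cols})")
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            edges.append((i, r * cols + (c + 1) % cols))
            edges.append((i, ((r + 1) % rows) * cols + c))
    return _graph_from_edges(rows * cols, edges)


def dodecahedron() -> DependenceGraph:
    """The dodecahedral graph (20 nodes, 30 edges, 3-regular): a spherical
    dependence pattern carrying a single 2-dimensional cavity."""
    g = nx.dodecahedral_graph()
    return _graph_from_edges(g.number_of_nodes(), g.edges())


# ---------------------------------------------------------------------------
# Quotient-polygon sampling


def _tile_points(pts: np.ndarray, spec: PolygonQuotientSpec) -> tuple[np.ndarray, np.ndarray]:
    """3x3 tiling of the fundamental rectangle, honouring identifications.

    Point coordinates are (x, y) with x in [0, cols) and y in [0, rows).
    Copies along a non-wrapping axis are pushed far away: they only bound
    the Voronoi cells of the central copy and carry no adjacency (flagged
    as padding in the returned per-copy mask).
    """
    w, h = float(spec.cols), float(spec.rows)
    far = 10.0 * (w + h)
    tiles = []
    real = []
    offsets = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1),
               (1, 1), (1, -1), (-1, 1), (-1, -1)]
    for dx, dy in offsets:
        q = pts.copy()
        is_real = True
        if dx != 0:
            if spec.wrap_cols:
                if spec.reverse_cols and dx % 2 != 0:
                    q[:, 1] = h - q[:, 1]
                q[:, 0] = q[:, 0] + dx * w
            else:
                q[:, 0] = q[:, 0] + dx * (w + far)
                is_real = False
        if dy != 0:
            if spec.wrap_rows:
                if spec.reverse_rows and dy % 2 != 0:
                    q[:, 0] = w - q[:, 0]
                q[:, 1] = q[:, 1] + dy * h
            else:
                q[:, 1] = q[:, 1] + dy * (h + far)
                is_real = False
        tiles.append(q)
        real.append(np.full(len(q), is_real))
    return np.vstack(tiles), np.concatenate(real)


def _voronoi_adjacency(
    tiled: np.ndarray, real: np.ndarray, n: int, scale: float
) -> set[tuple[int, int]]:
    """Edges of the central copy from Voronoi neighbourhood on the tiling.

    Two nodes are adjacent iff their Voronoi cells share a ridge of positive
    length; zero-length ridges (cocircular degeneracies, e.g. the diagonals
    of a square lattice) are discarded, as are ridges into padding copies.
    """
    vor = Voronoi(tiled)
    tol = 1e-9 * scale
    edges: set[tuple[int, int]] = set()
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n and q >= n:
            continue  # ridge not touching the central copy
        if not (real[p] and real[q]):
            continue  # padding along a non-wrapped axis
        if -1 in rv:
            continue  # unbounded ridge on the outer boundary of the tiling
        v = vor.vertices[list(rv)]
        if len(v) < 2 or np.linalg.norm(v[0] - v[1]) <= tol:
            continue
        a, b = int(p % n), int(q % n)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return edges


def sample_quotient_graph(
    spec: PolygonQuotientSpec,
    n_points: int | None = None,
    seed: int = 0,
    mode: str = "regular",
    max_retries: int = 5,
) -> DependenceGraph:
    """Sample a dependence graph from a flat polygon with identified edges.

    ``mode='regular'`` places one point per cell centre of a
    ``rows x cols`` grid (reproducing the periodic-lattice constructors);
    ``mode='uniform_random'`` draws ``n_points`` uniformly from the
    rectangle.  Adjacency comes from the Voronoi tessellation computed on a
    3x3 tiling of the fundamental domain so that it respects the edge
    identifications; boundary copies are merged back onto the fundamental
    domain.  Degenerate or disconnected random samples are retried with an
    incremented seed.
    """
    if mode not in ("regular", "uniform_random"):
        raise ValueError(f"unknown mode {mode!r}")
    scale = float(spec.rows + spec.cols)
    if mode == "regular":
        xs = (np.arange(spec.cols) + 0.5)
        ys = (np.arange(spec.rows) + 0.5)
        # row-major layout to match torus_grid node numbering
        pts = np.array([(x, y) for y in ys for x in xs], dtype=float)
        tiled, real = _tile_points(pts, spec)
        edges = _voronoi_adjacency(tiled, real, len(pts), scale)
        return _graph_from_edges(len(pts), sorted(edges))

    if n_points is None or n_points < 4:
        raise ValueError("uniform_random mode requires n_points >= 4")
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        pts = np.column_stack(
            [rng.uniform(0, spec.cols, n_points), rng.uniform(0, spec.rows, n_points)]
        )
        try:
            tiled, real = _tile_points(pts, spec)
            edges = _voronoi_adjacency(tiled, real, n_points, scale)
            g = _graph_from_edges(n_points, sorted(edges))
        except Exception as err:  # qhull degeneracy
            last_err = err
            continue
        if g.is_connected():
            return g
        last_err = ValueError("sampled graph is disconnected")
    raise RuntimeError(
        f"could not sample a valid graph in {max_retries} attempts: {last_err}"
    )


def shortest_path_distances(g: DependenceGraph) -> np.ndarray:
    """All-pairs hop-count distance matrix (BFS); unreachable pairs get the
    ``UNREACHABLE`` sentinel."""
    rows = [i for i, j in g.edges] + [j for i, j in g.edges]
    cols = [j for i, j in g.edges] + [i for i, j in g.edges]
    a = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(g.n_nodes, g.n_nodes)
    )
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    out = np.full(d.shape, UNREACHABLE, dtype=np.int64)
    finite = np.isfinite(d)
    out[finite] = d[finite].astype(np.int64)
    return out
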
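"""Dependence-graph constructors and hop-count metrics."""

from collections import deque

import numpy as np
import pytest

from topotsa.graphs import (
    PolygonQuotientSpec,
    circular_ladder,
    dodecahedron,
    double_circular_ladder,
    sample_quotient_graph,
    shortest_path_distances,
    torus_grid,
)


def bfs_distances(n_nodes, edges):
    """Independent BFS oracle."""
    adj = [[] for _ in range(n_nodes)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    d = np.full((n_nodes, n_nodes), -1, dtype=int)
    for s in range(n_nodes):
        d[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if d[s, v] < 0:
                    d[s, v] = d[s, u] + 1
                    q.append(v)
    return d


@pytest.mark.parametrize(
    "factory,n_nodes,n_edges,degree",
    [
        (lambda: circular_ladder(15), 30, 45, 3),
        (lambda: torus_grid(9, 17), 153, 306, 4),
        (dodecahedron, 20, 30, 3),
    ],
)
def test_constructor_counts_and_regularity(factory, n_nodes, n_edges, degree):
    g = factory()
    assert g.n_nodes == n_nodes
    assert g.n_edges == n_edges
    assert np.all(g.degrees() == degree)
    assert g.is_connected()


def test_double_circular_ladder_structure():
    g = double_circular_ladder(8)
    assert g.n_nodes == 32
    assert g.is_connected()
    # two 3-regular lobes plus one rung-aligned pair of bridges
    assert g.n_edges == 2 * 24 + 2
    degrees = g.degrees()
    assert sorted(set(degrees.tolist())) == [3, 4]
    assert int(np.sum(degrees == 4)) == 4  # the four bridge endpoints
    # single-bridge variant is a wedge of the two lobes
    assert double_circular_ladder(8, n_bridges=1).n_edges == 49


@pytest.mark.parametrize(
    "bad", [lambda: circular_ladder(2), lambda: double_circular_ladder(1),
            lambda: torus_grid(2, 5), lambda: torus_grid(5, 2)]
)
def test_constructors_reject_degenerate_sizes(bad):
    with pytest.raises(ValueError):
        bad()


def test_circular_ladder_distances_match_bfs_oracle():
    g = circular_ladder(15)
    d = shortest_path_distances(g)
    expected = bfs_distances(g.n_nodes, g.edges)
    assert np.array_equal(d, expected)
    # the worked example geometry: node 1 adjacent to 2, five hops to node 6
    assert d[0, 1] == 1
    assert d[0, 5] == 5


def test_circular_ladder_vertex_transitive():
    d = shortest_path_distances(circular_ladder(15))
    rows = {tuple(sorted(r)) for r in d.tolist()}
    assert len(rows) == 1


def test_torus_distances_are_l1_on_periodic_lattice():
    rows, cols = 9, 17
    d = shortest_path_distances(torus_grid(rows, cols))
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0)
    assert d.max() == rows // 2 + cols // 2  # 12
    # spot-check the circular L1 metric
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b = rng.integers(0, rows * cols, 2)
        ra, ca = divmod(int(a), cols)
        rb, cb = divmod(int(b), cols)
        dr = min(abs(ra - rb), rows - abs(ra - rb))
        dc = min(abs(ca - cb), cols - abs(ca - cb))
        assert d[a, b] == dr + dc


def test_dodecahedron_girth_and_diameter():
    g = dodecahedron()
    d = shortest_path_distances(g)
    assert d.max() == 5
    # girth 5: no 3- or 4-cycles through any edge
    adj = g.adjacency()
    assert np.trace(np.linalg.matrix_power(adj, 3)) == 0
    neighbors = [set(np.flatnonzero(adj[i])) for i in range(g.n_nodes)]
    for i, j in g.edges:
        assert not (neighbors[i] & neighbors[j])          # no triangle
    for i in range(g.n_nodes):
        for j in range(i + 1, g.n_nodes):
            if d[i, j] == 2:
                assert len(neighbors[i] & neighbors[j]) == 1  # no square


@pytest.mark.parametrize(
    "factory",
    [lambda: circular_ladder(6), lambda: double_circular_ladder(4),
     lambda: torus_grid(4, 5), dodecahedron],
)
def test_distance_matrix_is_a_metric(factory):
    d = shortest_path_distances(factory())
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0)
    adj = factory().adjacency()
    assert np.array_equal(d == 1, adj == 1)
    # exhaustive triangle inequality
    n = d.shape[0]
    through = d[:, None, :] + d[None, :, :].transpose(2, 1, 0)
    assert np.all(d[:, :, None] <= d[:, None, :] + d[None, :, :])


def test_quotient_regular_torus_equals_lattice_constructor():
    spec = PolygonQuotientSpec(rows=9, cols=17)
    g = sample_quotient_graph(spec, mode="regular")
    assert g.n_nodes == 153
    assert set(g.edges) == set(torus_grid(9, 17).edges)


def test_quotient_cylinder_degrees():
    spec = PolygonQuotientSpec(rows=5, cols=8, wrap_rows=False, wrap_cols=True)
    g = sample_quotient_graph(spec, mode="regular")
    degrees = g.degrees().reshape(5, 8)
    assert np.all(degrees[0] == 3) and np.all(degrees[-1] == 3)
    assert np.all(degrees[1:-1] == 4)


def test_quotient_uniform_random_connected_over_seeds():
    spec = PolygonQuotientSpec(rows=9, cols=17)
    for seed in range(3):
        g = sample_quotient_graph(spec, n_points=200, seed=seed, mode="uniform_random")
        assert g.n_nodes == 200
        assert g.is_connected()


def test_quotient_rejects_bad_arguments():
    spec = PolygonQuotientSpec(rows=9, cols=17)
    with pytest.raises(ValueError):
        sample_quotient_graph(spec, n_points=3, mode="uniform_random")
    with pytest.raises(ValueError):
        sample_quotient_graph(spec, mode="nope")
    with pytest.raises(ValueError):
        PolygonQuotientSpec(rows=2, cols=5)
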
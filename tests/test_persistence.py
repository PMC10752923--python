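"""Vietoris-Rips persistence against the brute-force oracle, plus summaries."""

import numpy as np
import pytest

from topotsa.persistence import (
    PersistenceDiagram,
    prominent_features,
    total_persistence,
    vr_persistence,
)
from vr_bruteforce import vr_bruteforce


def as_tuples(pd: PersistenceDiagram, dims=(0, 1, 2)):
    out = []
    for d, b, dd in zip(pd.dims, pd.births, pd.deaths):
        if d in dims:
            out.append((int(d), round(float(b), 10), round(float(dd), 10) if np.isfinite(dd) else np.inf))
    return sorted(out)


def random_metric(rng, n, tie_round=None):
    x = rng.uniform(0.05, 1.0, (n, n))
    if tie_round is not None:
        x = np.round(x, tie_round)
    d = np.triu(x, 1)
    d = d + d.T
    return d


def test_square_cycle_births_at_side_dies_at_diagonal(square_distance):
    pd = vr_persistence(square_distance, max_dim=2)
    ones = pd.features(1)
    assert ones.shape[0] == 1
    assert tuple(ones[0]) == (1.0, 1.0, 1.5)
    assert np.sum(np.isinf(pd.deaths)) == 1  # single essential component


def test_single_point_and_input_validation():
    pd = vr_persistence(np.zeros((1, 1)), max_dim=1)
    assert as_tuples(pd) == [(0, 0.0, np.inf)]
    with pytest.raises(ValueError):
        vr_persistence(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        vr_persistence(np.array([[1.0, 1.0], [1.0, 1.0]]))  # nonzero diagonal
    with pytest.raises(ValueError):
        vr_persistence(np.zeros((2, 2)), max_dim=3)


@pytest.mark.parametrize("tie_round", [None, 1])
def test_oracle_equivalence_on_random_six_point_spaces(tie_round):
    rng = np.random.default_rng(42 if tie_round is None else 43)
    for _ in range(25):
        d = random_metric(rng, 6, tie_round)
        got = as_tuples(vr_persistence(d, max_dim=1), dims=(0, 1))
        expected = sorted(
            (k, round(b, 10), round(dd, 10) if np.isfinite(dd) else np.inf)
            for k, b, dd in vr_bruteforce(d, max_dim=1)
        )
        assert got == expected


def test_oracle_equivalence_including_dimension_two():
    rng = np.random.default_rng(7)
    for _ in range(10):
        d = random_metric(rng, 7)
        got = as_tuples(vr_persistence(d, max_dim=2))
        expected = sorted(
            (k, round(b, 10), round(dd, 10) if np.isfinite(dd) else np.inf)
            for k, b, dd in vr_bruteforce(d, max_dim=2)
        )
        assert got == expected


def test_scale_equivariance():
    rng = np.random.default_rng(3)
    d = random_metric(rng, 8)
    base = vr_persistence(d, max_dim=2)
    scaled = vr_persistence(2.5 * d, max_dim=2)
    assert np.array_equal(base.dims, scaled.dims)
    assert np.allclose(2.5 * base.births, scaled.births)
    finite = np.isfinite(base.deaths)
    assert np.allclose(2.5 * base.deaths[finite], scaled.deaths[finite])
    for k in (0, 1, 2):
        assert total_persistence(scaled, k) == pytest.approx(
            2.5 * total_persistence(base, k)
        )


def test_monotone_transform_preserves_feature_counts():
    rng = np.random.default_rng(11)
    d = random_metric(rng, 8)
    base = vr_persistence(d, max_dim=1)
    warped = vr_persistence(np.sqrt(d), max_dim=1)
    for k in (0, 1):
        assert len(base.features(k)) == len(warped.features(k))


def test_total_persistence_arithmetic_and_linearity():
    pd = PersistenceDiagram(
        dims=np.array([0, 1, 1]),
        births=np.array([0.0, 0.2, 0.1]),
        deaths=np.array([np.inf, 0.5, 0.9]),
    )
    assert total_persistence(pd, 1) == pytest.approx(1.1)
    assert total_persistence(pd, 0) == 0.0  # essential excluded
    assert total_persistence(pd, 0, truncate_at=2.0) == pytest.approx(2.0)
    assert total_persistence(pd, 2) == 0.0
    other = PersistenceDiagram(
        dims=np.array([1]), births=np.array([0.0]), deaths=np.array([0.3])
    )
    both = pd.concat(other)
    assert total_persistence(both, 1) == pytest.approx(
        total_persistence(pd, 1) + total_persistence(other, 1)
    )


def test_prominent_feature_counting():
    pd = PersistenceDiagram(
        dims=np.array([1, 1, 1, 2]),
        births=np.array([0.1, 0.1, 0.1, 0.2]),
        deaths=np.array([0.9, 0.6, 0.15, 0.25]),
    )
    assert prominent_features(pd, 1, rel_threshold=0.5) == 2
    assert prominent_features(pd, 1, rel_threshold=0.9) == 1
    assert prominent_features(pd, 2) == 1
    assert prominent_features(pd, 0) == 0  # empty dimension
    with pytest.raises(ValueError):
        prominent_features(pd, 1, rel_threshold=0.0)


def test_explicit_threshold_truncates_with_infinite_survivors():
    # circle of 6 points: cycle born early, killed late; cutting the
    # filtration before the death leaves an essential 1-class
    theta = 2 * np.pi * np.arange(6) / 6
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    full = vr_persistence(d, max_dim=1)
    ones = full.features(1)
    assert ones.shape[0] == 1 and np.isfinite(ones[0, 2])
    cut = vr_persistence(d, max_dim=1, thresh=(ones[0, 1] + ones[0, 2]) / 2)
    assert np.isinf(cut.features(1)[0, 2])


def test_sizing_rule_for_cycle_detection():
    """With K=2 the main cycle needs graph diameter above 2K: a 16-node
    ladder ring is detected, an 8-node one is washed out."""
    from topotsa.graphs import circular_ladder, shortest_path_distances
    from topotsa.mixing import mixing_model, theoretical_correlation

    def theoretical_diagram(n_rungs):
        w = mixing_model(circular_ladder(n_rungs), K=2).W
        r = theoretical_correlation(w)
        d = 1 - r**2  # noiseless coherence is squared correlation
        np.fill_diagonal(d, 0)
        return vr_persistence(0.5 * (d + d.T), max_dim=1)

    big = theoretical_diagram(8)    # P=16, diameter 5 > 2K
    small = theoretical_diagram(4)  # P=8, diameter 3 < 2K... barely any cycle
    assert prominent_features(big, 1) == 1
    big_life = big.lifetimes(1).max()
    small_life = small.lifetimes(1).max() if len(small.features(1)) else 0.0
    assert big_life > 2 * small_life
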
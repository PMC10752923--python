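"""Periodogram, smoothing, band coherence, and the coherence distance."""

import numpy as np
import pytest

from topotsa.ar2 import ar2_theoretical_spectrum, band_preset, simulate_ar2_panel
from topotsa.mixing import MultivariateSeries, simulate_network_series
from topotsa.graphs import circular_ladder, shortest_path_distances
from topotsa.spectral import (
    band_coherence,
    coherence_distance,
    default_half_width,
    kernel_weights,
    periodogram,
    smooth_periodogram,
)


def white_noise_series(t, p, seed=0, sr=100.0):
    rng = np.random.default_rng(seed)
    return MultivariateSeries(y=rng.standard_normal((t, p)), sampling_rate_hz=sr)


def test_parseval_bin_average_equals_sample_variance():
    y = white_noise_series(1024, 3, seed=5)
    raw = periodogram(y)
    power = np.abs(raw.coeffs) ** 2
    var = y.y.var(axis=0)  # channels are mean-centred internally
    assert np.allclose(power.mean(axis=0), var, rtol=1e-8)


def test_pure_cosine_concentrates_on_its_bin():
    t, sr = 512, 100.0
    k = 32
    time = np.arange(t)
    y = MultivariateSeries(
        y=np.column_stack(
            [np.cos(2 * np.pi * k * time / t), np.sin(2 * np.pi * k * time / t)]
        ),
        sampling_rate_hz=sr,
    )
    raw = periodogram(y)
    power = np.abs(raw.coeffs[:, 0]) ** 2
    mass = power[k] + power[t - k]
    assert mass == pytest.approx(power.sum(), rel=1e-10)


def test_raw_periodogram_matrices_are_rank_one_psd():
    y = white_noise_series(128, 4, seed=1)
    raw = periodogram(y)
    for k in (1, 17, 60):
        m = raw.matrix(k)
        assert np.allclose(m, m.conj().T)
        ev = np.linalg.eigvalsh(m)
        assert ev.min() > -1e-12
        assert np.sum(ev > 1e-10 * ev.max()) == 1


def test_smoothed_diag_is_flat_for_white_noise_with_reduced_variance():
    y = white_noise_series(4096, 2, seed=3)
    raw = periodogram(y)
    h = 16
    sm = smooth_periodogram(raw, half_width=h)
    raw_diag = np.abs(raw.coeffs[:, 0]) ** 2
    sm_diag = sm.diagonal()[:, 0]
    ratio = sm_diag.var() / raw_diag.var()
    assert ratio == pytest.approx(1 / (2 * h + 1), rel=0.35)
    assert sm_diag.mean() == pytest.approx(1.0, abs=0.1)


def test_identity_kernel_with_zero_width_is_a_no_op():
    y = white_noise_series(256, 2, seed=4)
    raw = periodogram(y)
    sm = smooth_periodogram(raw, kernel="identity", half_width=0)
    assert np.allclose(sm.matrix(10), raw.matrix(10))


def test_kernel_validation():
    w = kernel_weights("daniell", 3)
    assert w.sum() == pytest.approx(1.0) and np.all(w > 0)
    with pytest.raises(ValueError):
        kernel_weights("boxcar9000", 3)
    with pytest.raises(ValueError):
        kernel_weights("daniell", -1)


def test_smoothed_ar2_spectrum_peaks_at_band_frequency(alpha_band):
    panel = simulate_ar2_panel(alpha_band, n_series=3, n_samples=2000, seed=6)
    y = MultivariateSeries(y=panel.z, sampling_rate_hz=alpha_band.sampling_rate_hz)
    sm = smooth_periodogram(periodogram(y), half_width=7)
    diag = sm.diagonal().mean(axis=1)
    freqs = sm.freqs_hz
    peak = freqs[np.argmax(diag)]
    assert abs(peak - alpha_band.peak_freq_hz) <= 1.0
    # and the theoretical spectrum agrees on the argmax location
    theo = ar2_theoretical_spectrum(alpha_band, freqs)
    assert abs(freqs[np.argmax(theo)] - peak) <= 1.0


def test_independent_channels_have_low_coherence():
    y = white_noise_series(4000, 2, seed=8)
    sm = smooth_periodogram(periodogram(y), half_width=10)
    c = band_coherence(sm, (10, 20)).C
    assert c[0, 0] == 1.0 and c[1, 1] == 1.0
    assert 0 <= c[0, 1] < 0.15


def test_band_coherence_validation_and_range(alpha_band):
    g = circular_ladder(15)
    y = simulate_network_series(g, alpha_band, K=2, n_samples=1000, seed=10)
    sm = smooth_periodogram(periodogram(y))
    c = band_coherence(sm, (8, 12)).C
    assert np.all((c >= 0) & (c <= 1))
    assert np.allclose(c, c.T)
    with pytest.raises(ValueError):
        band_coherence(sm, (49.99, 49.991))  # narrower than one bin
    with pytest.raises(ValueError):
        sm.band_bins((12, 8))


def test_network_coherence_orders_by_graph_distance(alpha_band):
    g = circular_ladder(15)
    d = shortest_path_distances(g)
    y = simulate_network_series(g, alpha_band, K=2, n_samples=4000, seed=11)
    sm = smooth_periodogram(periodogram(y))
    c = band_coherence(sm, (8, 12)).C
    close = c[d == 1]
    far = c[d == 4]
    assert close.mean() > far.mean()
    assert np.mean(close[:, None] > far[None, :]) > 0.9


def test_coherence_distance_transforms():
    c = np.array([[1.0, 0.76, 0.0], [0.76, 1.0, 1.0], [0.0, 1.0, 1.0]])
    d1 = coherence_distance(c, "one_minus").D
    assert d1[0, 1] == pytest.approx(0.24)
    assert d1[0, 2] == 1.0 and d1[1, 2] == 0.0
    assert np.all(np.diag(d1) == 0)
    d2 = coherence_distance(c, "sqrt_one_minus").D
    off = ~np.eye(3, dtype=bool)
    assert np.all(d2[off] >= d1[off] - 1e-12)
    with pytest.raises(ValueError):
        coherence_distance(c + 1.0)
    with pytest.raises(ValueError):
        coherence_distance(c, "nope")


def test_pipeline_is_deterministic(alpha_band):
    from topotsa.pipeline import coherence_distance_matrix

    g = circular_ladder(6)
    y = simulate_network_series(g, alpha_band, K=2, n_samples=512, seed=12)
    d1 = coherence_distance_matrix(y)
    d2 = coherence_distance_matrix(y)
    assert np.array_equal(d1, d2)
    assert default_half_width(512) == 12
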
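# topotsa

Simulate multivariate time series whose frequency-specific dependence
network has a **prescribed topology** — one cycle, two cycles, a torus, a
sphere — and recover that topology with coherence-based Vietoris–Rips
persistent homology.  Built for researchers who evaluate topological data
analysis (TDA) methods on brain-signal-like data (EEG/LFP), where no real
recording comes with a known ground-truth dependence structure: the only way
to measure sensitivity, specificity, or test power of a TDA pipeline is
simulation under a user-specified truth.

## The model

Each channel observes a distance-weighted mixture of latent band-limited
oscillations attached to the nodes of a dependence graph *G*:

```
Y_p(t) = Σ_q W_pq Z_q(t) + ε_p(t),     W_pq = 1/(1 + d_G(p,q))  if d_G(p,q) ≤ K, else 0
```

* **Latents** `Z_q` are iid AR(2) processes `Z(t) = φ₁Z(t−1) + φ₂Z(t−2) + W(t)`
  whose characteristic roots `M·exp(±i2πf/SR)` put the spectral peak at a
  chosen frequency `f` (e.g. the alpha band, 10 Hz at SR = 100 Hz), with
  `φ₁ = (2/M)cos(2πf/SR)`, `φ₂ = −1/M²`, standardised to unit variance.
* **Mixing** decays with hop distance and cuts off at `K` (default 2):
  channels near each other in *G* share many latents and are strongly
  coherent; channels more than `2K` apart share none and are independent.
* **Analysis** estimates the spectral matrix by a Daniell-smoothed
  periodogram, forms band coherence `C_pq = |f̂_pq|²/(f̂_pp f̂_qq)`, converts
  it into the distance `D_pq = 1 − C_pq`, and computes the Vietoris–Rips
  persistence diagram of the resulting finite metric space.  Prominent
  off-diagonal features of dimension *k* recover the Betti numbers of the
  prescribed structure (a torus: β₁ = 2, β₂ = 1).
* **Inference** uses the total persistence `P_k = Σᵢ (dᵢᵏ − bᵢᵏ)` as a scalar
  summary for SNR-robustness curves and bootstrap two-group comparisons.

Graph constructors include circular ladders (one main cycle), double
circular ladders (two main cycles), periodic grids (torus), the dodecahedral
graph (sphere), and a generic sampler that draws nodes from a flat polygon
with identified edges (quotient representation) and reads adjacency off a
periodic Voronoi tessellation.

The Vietoris–Rips engine is implemented in-package (numba-accelerated
coboundary reduction with clearing and emergent-pair shortcuts, ℤ/2
coefficients, exact integer-quantised filtrations) and is validated against
a brute-force boundary-matrix reducer in the test suite.

## Worked example

Recover the Betti numbers of a torus from a simulated 153-channel series:

```python
import numpy as np
from topotsa import (band_preset, torus_grid, simulate_network_series,
                     coherence_distance_matrix, vr_persistence,
                     prominent_features, total_persistence)

band = band_preset("alpha")          # AR(2) peak at 10 Hz, SR 100 Hz, M = 1.05
g = torus_grid(9, 17)                # P = 153 channels on a periodic grid
y = simulate_network_series(g, band, K=3, n_samples=2000, seed=0)
D = coherence_distance_matrix(y)     # mid-band (8-12 Hz) coherence distance
diagram = vr_persistence(D, max_dim=2)

for k in (0, 1, 2):
    print(f"dim {k}: {prominent_features(diagram, k):3d} prominent features, "
          f"total persistence P_{k} = {total_persistence(diagram, k):.3f}")
```

prints

```
dim 0: 152 prominent features, total persistence P_0 = 52.851
dim 1:   2 prominent features, total persistence P_1 = 11.924
dim 2:   1 prominent features, total persistence P_2 = 1.216
```

The two prominent 1-dimensional features (lifetimes 0.51 and 0.46, an order
of magnitude above the secondary-cycle noise near the diagonal) are the two
essential circles of the torus; the single prominent 2-dimensional feature
is its cavity — exactly β₁ = 2, β₂ = 1.  The 152 dim-0 features are the
mergers of the 153 channels into one component; their count carries no
topology beyond connectivity and shrinks with noise (see the SNR study).

## Command line

```sh
topotsa presets torus > torus.yaml         # the four canonical configs
topotsa simulate  -c torus.yaml -o run/    # series + graph + weights
topotsa persist   run/series.tsv -c torus.yaml -o run/ph/   # diagram + summary
topotsa snr-study -c sphere.yaml -o snr/   # P_k vs signal-to-noise ratio
topotsa infer     -c infer.yaml  -o inf/   # one-cycle vs two-cycle bootstrap
```

Every command writes a `resolved_config.yaml` with all defaults filled in;
re-running from it reproduces the outputs byte-identically.

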
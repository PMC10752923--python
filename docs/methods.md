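# Methods

This note documents the generative model, the estimation pipeline, the
persistence engine, the simulation studies, and the numerical and design
choices behind them.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model

**Latent oscillations.**  Each node of the dependence graph carries an
independent AR(2) process `Z(t) = φ₁Z(t−1) + φ₂Z(t−2) + W(t)` with Gaussian
innovations.  The characteristic roots are `M·exp(±i2πψ)` with normalised
peak frequency `ψ = f/SR ∈ (0, ½)` and root modulus `M > 1`, giving
`φ₁ = (2/M)cos(2πψ)` and `φ₂ = −1/M²`; both roots lie outside the unit
circle, so every spec the constructor can produce is stationary and causal.
The spectrum `σ²/|1 − φ₁e^{−i2πν} − φ₂e^{−i4πν}|²` concentrates around `f`,
more sharply as `M → 1`.

Parameters and defaults:

| parameter | meaning | default | why |
|---|---|---|---|
| `f` (Hz) | spectral peak | 10 (alpha preset) | canonical EEG band; presets delta/theta/alpha/beta = 2/5/10/19.5 Hz |
| `SR` (Hz) | sampling rate | 100 | typical decimated electrophysiology rate |
| `M` | root modulus | 1.05 | close to 1: band-limited but numerically comfortable; exposed in config |
| `σ` | innovation sd | 1 | scale is irrelevant after standardisation |
| burn-in | discarded samples | 500 | ≈ 10 spectral-peak periods; transients from the zero start decay as `M^{−t}` |

Simulated panels are divided by the closed-form stationary standard
deviation (`σ²(1−φ₂)/((1+φ₂)((1−φ₂)²−φ₁²))`), not the sample sd, so the
latent variance is exactly 1 and mixtures have exactly the covariance the
weights imply.  Innovations are Gaussian — the noise model of the group
study is Gaussian anyway, and it keeps every draw reproducible from one
seed.  Seeding uses `numpy.random.SeedSequence` spawning: one child stream
per latent series (so series *i* is identical whatever the panel width) and
a separate child for observation noise.

**Mixing.**  With hop-count distances `d_G` from all-pairs BFS, the weight
matrix is `W_pq = g(d_G(p,q))` for `d_G ≤ K`, else 0, with
`g ∈ {1/(1+x), 1/(1+x²), e^{−x}}` (default the slowest decay, `1/(1+x)`,
and `K = 2`; the torus uses `K = 3`).  Faster decays sharpen the distance
contrast but weaken long-range coherence, making features harder to detect.
Because the latents are unit-variance and independent, the noiseless signal
covariance is exactly `WWᵀ`, which yields closed-form oracles: correlations
`R_pq = (WWᵀ)_pq/√(V_pp V_qq)` with `V = WWᵀ + σ_ε²I`, and noiseless
coherence `R_pq²`.  For the 15-rung circular ladder at `K = 2` the
shared-latent expansion gives `(WWᵀ)₁₂ = 10/6` and `(WWᵀ)₁₁ = 79/36`, hence
`Corr(Y₁,Y₂) = 60/79 ≈ 0.76`, and `Corr(Y₁,Y₆) = 0` because nodes 1 and 6
are five hops apart and share no latent within the cutoff.

**Noise and SNR.**  Observation noise is iid Gaussian per channel and time
point.  The signal-to-noise ratio is defined with the channel-averaged
signal variance, `σ_ε = √(mean_p (WWᵀ)_pp / SNR)`; the paper-style global
`σ_S²` does not say how to aggregate heterogeneous channels, and the
channel average keeps the calibration graph-independent.

## Spectral estimation

Channels are mean-centred; no taper is applied by default (a taper option
exists but the AR(2) spectra here are smooth enough that leakage is not a
concern at T ≥ 500).  Fourier coefficients use the `1/√T` normalisation, so
the periodogram `I(ω_k) = d(ω_k)d(ω_k)*` is asymptotically unbiased for the
spectral density and the bin-average of its diagonal equals the sample
variance (the Parseval check in the tests).  Smoothing convolves the
matrix sequence circularly over the full Fourier grid with a normalised
non-negative kernel — default Daniell (boxcar) with half-width
`⌈√T/2⌉` bins (23 bins at T = 2000, i.e. a ±1.15 Hz window at SR = 100) —
which keeps every smoothed matrix Hermitian positive semidefinite.

Band coherence averages the smoothed matrices over the Fourier bins of the
band and then forms `|f̄_pq|²/(f̄_pp f̄_qq)`; smoothing *before* the ratio is
essential (raw rank-1 periodogram coherence is identically 1).  Averaging
per-bin coherences instead is available as a manual alternative but the
matrix-level average is the default: it is the band-level analogue of the
coherence formula itself.  The analysis bands default to mid = 8–12 Hz and
high = 30–50 Hz at SR = 100 (the bands are never pinned numerically by the
underlying studies; these brackets place the alpha peak centrally).  With
zero observation noise the model's true coherence is frequency-constant, so
the band choice affects only estimation variance, not the target.

The distance transform defaults to `G(x) = 1 − x`; `√(1−x)` is provided
(both are monotone-decreasing, so the persistence pairing is identical up
to a monotone change of filtration scale — a tested invariant).

Implementation note: per-frequency P×P matrices are never materialised as a
T×P×P array.  The estimate stores the T×P coefficient matrix plus the
kernel, and any smoothed or band-averaged matrix is assembled on demand as
a weighted outer-product sum (one P×F·F×P product), keeping memory linear
in T and P even at P = 153, T = 2000.

## Vietoris–Rips persistence

The filtration is the standard VR complex of the distance matrix (a simplex
enters at its diameter).  Homology uses ℤ/2 coefficients.  Pairs are
computed dimension by dimension in the cohomology order: dimension 0 by
Kruskal union-find over edges; dimension d ≥ 1 by left-to-right reduction
of the anti-transposed coboundary matrix — columns are d-simplices in
decreasing filtration order, entries their (d+1)-cofacets, the pivot the
cofacet minimal in filtration order — with clearing (simplices that were
pivots one dimension below are skipped) and the emergent-pair shortcut (the
first equal-diameter cofacet in ascending-vertex enumeration is the pivot
of the unreduced column; if unclaimed, the column is done in O(P)).
Reduced columns are stored in factored form and their coboundaries
re-enumerated on demand, so the top-dimensional simplices are never
enumerated (at P = 153 and max_dim = 2 there are ~2.2·10⁷ tetrahedra; only
their ≤ P-element cofacet lists of ~5.8·10⁵ triangles are touched).

Numerical choices:

* distances are quantised to integer levels (indices into the sorted unique
  values), so all filtration comparisons are exact and ties are resolved by
  colexicographic simplex rank, lower dimension first;
* the filtration is truncated at the enclosing radius `min_p max_q D_pq`,
  beyond which the complex is a cone: the diagram equals the full
  filtration's, with exactly one essential dim-0 class.  An explicit
  smaller threshold is allowed; classes alive at it are reported with
  death = ∞;
* zero-persistence pairs are dropped from diagrams (they are still used
  internally for clearing);
* the essential dim-0 class is excluded from total persistence `P₀` by
  default (it has no finite lifetime; a `truncate_at` option clips instead);
* empirical Betti counts use a relative lifetime threshold: a dim-k feature
  is *prominent* if its lifetime is at least `rel_threshold` (default 0.5)
  times the longest dim-k lifetime.  The underlying studies separate "main"
  from "secondary" cycles only visually; the 0.5 ratio is this package's
  operationalisation and is reported alongside the full diagram so users
  can re-threshold.

Correctness is anchored by a brute-force boundary-matrix reducer in the
test suite (full simplexwise filtration, Python sets), checked on random
6–7 point metric spaces with and without ties, plus property tests for
scale equivariance and monotone-transform invariance.

A sizing rule follows from the cutoff: a cycle is only detectable if the
subgraph around it has diameter above `2K` (channels across the cycle must
*lose* coherence).  A 16-node ladder ring at `K = 2` is the smallest
comfortable one-cycle example; the two-cycle graph needs ~32 nodes.  The
tests exercise this rule on the closed-form (noiseless) distance matrices.

## Simulation studies and problem sizes

**SNR robustness.**  Dodecahedral (spherical) structure, `K = 2`,
alpha-band latents, T = 2000, SNR grid {0.25, 0.5, 1, 2, 4, 8, 16}, 50
replicates per grid point (the scaled-down default; the grid and replicate
count are configurable).  Expected and tested behaviour: mean `P₀`
strictly decreasing in SNR (noisy channels look mutually independent —
large distances, late mergers), mean `P₁` and `P₂` increasing (the
spherical pattern emerges from the noise floor).

**Two-group bootstrap comparison.**  Group models with equal node counts:
one cycle = 16-rung circular ladder (P = 32), two cycles = double circular
ladder of two 8-rung lobes joined by a rung-aligned pair of bridge edges
(P = 32).  Equal sizes are deliberate — with different P the dim-0 total
would differ mechanically and the comparison would not isolate topology.
N = 20 samples per group, T = 2000, SNR = 4, B = 200 bootstrap resamples of
each group mean (scaled from the N = 50 / B = 1000 design).  The dim-1
summaries separate cleanly (disjoint bootstrap IQRs; the 95% bootstrap
interval of the group difference excludes 0 — the interval is this
package's quantitative addition to the visual boxplot comparison).

A known limitation, measured rather than hidden: the *dim-0* bootstrap-mean
distributions of the two groups do **not** overlap under these defaults.
The per-sample dim-0 totals overlap heavily (the group offset of ~0.4 is
about one within-group sd), but T = 2000 band-averaged coherence estimates
are so stable that the bootstrap-of-the-mean spread (~sd/√N ≈ 0.1) resolves
the small structural offset that any second-cycle wiring introduces into
the merge profile.  The corresponding acceptance test is left failing by
design; making it pass would require either much noisier per-sample
summaries (shorter T, narrower smoothing) or groups whose local metric
structure is matched to well under 1%.

**What the generator does and does not emulate.**  It produces stationary,
linear, Gaussian, single-band multivariate series with symmetric,
zero-lag, frequency-constant dependence.  Real electrophysiology is
nonstationary, multi-band, lead-lagged, and spatially noise-correlated;
none of that is modelled (lead-lag mixing and time-varying weights are
explicit non-goals).  Passing tests therefore demonstrate that the
*pipeline* recovers prescribed topology under the model's assumptions —
not that it will on arbitrary real recordings.

## Other design choices

* The double-ladder join is not fully determined by the underlying studies;
  the constructor defaults to a rung-aligned pair of bridge edges
  (`n_bridges=2`, a figure-eight after contracting the bridge rung) with a
  single-bridge wedge variant available.
* The quotient-polygon sampler computes adjacency from a Voronoi
  tessellation of a 3×3 tiling of the fundamental rectangle (the standard
  trick for periodic tessellations): ridges of positive length define
  edges, which makes the regular-grid torus exactly the rook (4-neighbour)
  lattice — cocircular zero-length ridges (the square-lattice diagonals)
  are discarded.  Copies along non-identified axes are pushed far away and
  carry no adjacency, so cylinders get degree-3 boundary rows.  Degenerate
  or disconnected random samples are retried with an incremented seed,
  bounded at 5 attempts.
* Orientation-reversing identifications (Klein-bottle-style gluing) are
  implemented in the tiling transform but untested; the sphere is delivered
  via the dodecahedral graph, whose bigon quotient would be numerically
  awkward.
* All P latents share one band spec per experiment; multi-band mixtures are
  out of scope of the default pipeline.
* Runtime envelope on one CPU: one torus pipeline run (P = 153, T = 2000,
  max_dim = 2) takes ~10 s after JIT warm-up; the five-seed acceptance
  script ~1 min; the full test suite ~1 min.
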
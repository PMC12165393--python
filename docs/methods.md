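# Methods

## The degree of toroidality

Persistent homology summarizes a point cloud by barcodes: multisets of
(birth, death) filtration intervals for connected components (H0), loops
(H1) and cavities (H2) of the Vietoris–Rips filtration.  A torus has one
component, two independent loops and one cavity, so "torus-like" barcodes
have two long H1 bars and one long H2 bar, with everything else short.

The package turns this into a continuous score.  For bars
p = (x_p, x_p') and q = (x_q, x_q') the sup-norm cost is
max(|x_p − x_q|, |x_p' − x_q'|).  The bottleneck distance d_B(P, Q) is
the minimum over matchings of the maximum matched cost, with unmatched
bars allowed to pair with the diagonal at cost persistence/2 (the
standard convention; a strict-bijection variant is available behind a
flag).  Because d_B carries the units of the filtration, each barcode is
first divided by its internal spread

    u(P) = max over bar pairs of the sup-norm cost,

giving the normalized bottleneck distance
d̂_B(P, Q) = d_B(P/u(P), Q/u(Q)), clipped to [0, 1].  The degree of
toroidality is the pair Γ = (Γ1, Γ2) with

    Γ_d = 1 − d̂_B(τ_d, τ_d^ref),    d = 1, 2,

where the reference barcode set is built from a barcode set itself:
**data mode** keeps the two longest H1 bars and the longest H2 bar
verbatim; **self mode** keeps the longest H1 bar, stretches the
second-longest H1 bar to the same length, and keeps the longest H2 bar.
In both modes every other bar keeps its birth and is shrunk to the
minimum bar length of its dimension.  Ties among "longest" bars break by
earlier birth, then input order.  A complementary statistic is the
**H1/H2 gap**: the death radius of the longest H1 bar minus the birth
radius of the longest H2 bar.  In torus-like barcodes the loops outlive
the birth of the cavity (large positive gap); in barcodes where a cavity
only appears after the loops fill in, the gap is near zero or negative.

Numerical notes.  The bottleneck distance is computed by binary search
over the candidate costs (all pairwise and diagonal costs) with a
bipartite feasibility matching (`scipy` Hopcroft–Karp) at each threshold;
an exhaustive min-max matching enumeration is kept in the test suite as
an independent oracle.  `scale_factor` of a single-bar barcode falls back
to that bar's persistence; empty or all-identical barcodes raise rather
than return NaN.  Clipping events of d̂_B > 1 are recorded.

### What Γ resolves — and a known ceiling

Γ is invariant to rescaling either barcode (tested to 1e-9), so data at
different spatial or embedding scales are comparable.  Its ceiling for
finite samples is set by the third-longest H1 bar: on 400–1200 i.i.d.
points of the (a=5, c=10) torus the Rips filtration persistently carries
a ~3-unit-long third H1 bar, which costs ≈ 0.19 after normalization, so
clean-sample Γ1 saturates near 0.75–0.81 (Γ2 near 0.88–0.98) rather than
approaching 1.  Near-optimally spread (farthest-point) coverings shrink
that bar and push Γ1 toward 0.88+, showing it is a sampling artifact of
the measure's input, not of its definition.  The toy-torus validation
test asserts the idealized >0.9 level for both components and is
expected to fail at the i.i.d.-sampling conditions; the decay,
sigmoid-fittability and exact scale-invariance assertions pass.

## Grid-cell simulator

N independent inhomogeneous-Poisson neurons fire with rate

    λ_i(r, t) = [ (λ0 + Σ_k G(|r − r_ik|)) · (c1 + c2 Σ_μ A(ω_μ) cos(2π ω_μ t)) ]_+

with truncated Gaussian fields G(x) = G0/(2πσ²) · exp(−x²/2σ²) for
|x| < x0.  Defaults: λ0 = 0.05 Hz, G0 = 1.5 Hz·m², σ = 0.12 m,
x0 = 0.4 m, N = 75, hexagonal lattice of spacing 0.85 m in a 1.5 m
square arena.  Field centers are the lattice points within the arena
plus an x0 margin (so truncated tails at the walls are correct); each
neuron's lattice is shifted by an i.i.d. uniform offset within one unit
cell; orientation is 0° and shared.  Spikes are Poisson per 10 ms bin
with mean λ_i(r(t), t)·δt, placed uniformly within the bin.

The oscillator bank (`methods_default`) has m = 200 frequencies
log-spaced in [1, 50] Hz with amplitudes A(ω) = 0.25 ω^(−1/2); the grid
points nearest 4 Hz (eta) and 8 Hz (theta) are snapped onto those
frequencies with coefficients 0.5 and 0.8.  All oscillators share zero
phase at t = 0.  With c1 = 0, the modulation c2·[Σ]_+ depends only on
the *relative* amplitude profile: any global amplitude scaling is
canceled by the calibration of c2, defined as the reciprocal of the
time-averaged rectified oscillator sum.  The default calibration window
equals the default simulation horizon (1800 s at 10 ms), which makes
spike-count conservation between modulated and unmodulated runs exact by
construction over that horizon: a short window such as 36 s is biased
(~20% low) because the coherent zero phases at t = 0 make the early
rectified average unrepresentative (0.4254 over 36 s versus 0.5106 in
the long run).  Conservation along a moving trajectory additionally
carries a percent-level covariance term between the spatial rate and the
modulation, which the tests document.

The foraging trajectory is a 2D Ornstein–Uhlenbeck velocity process
(relaxation time 1 s, stationary mean speed 0.15 m/s) with reflecting
walls, sampled at 10 ms.  Over 30 minutes it covers ≥95% of 5 cm bins
and spends >90% of samples above the 2.5 cm/s movement threshold — the
regime the analysis assumes.  It does not reproduce the inhomogeneous
occupancy, resting bouts, or wall-following of real rodent behavior, so
simulation results quantify the method under idealized exploration.

`displace_fields` moves every field center by a fixed magnitude
(fraction × spacing) in an i.i.d. random direction (a Gaussian
alternative is a flag); `LatticeSpec(kind="square")` replaces the
hexagonal lattice for the square-grid control.

## The TDA pipeline

Spike trains → binned at 10 ms → Gaussian-smoothed → every 5th
population vector kept → the 15000 most active vectors (largest row
sum; a seeded uniform-random alternative for the sampling-choice
control) → centered PCA to 6 dimensions → density-filtered
farthest-point downsampling → Vietoris–Rips persistence to H2.

The smoothing width is a free parameter of this family of analyses.  A
sensitivity scan on 30-minute oscillation-modulated simulations (25, 50,
100, 200, 400 ms) shows the toroidal structure emerges robustly only for
widths ≳150 ms at these firing rates (~2.4 Hz mean): narrower kernels
leave too few spikes per population vector.  The package default is
**200 ms**, and the scan is reproducible with `TdaConfig(kernel_sigma=…)`.

Downsampling is the package's concrete realization of density-aware
reduction: points in the lowest decile of k-NN density (k = 15, distance
to the 15th neighbor) are dropped, then greedy maxmin selection picks
well-spread points; the start point derives from the config seed, making
the chain fully deterministic.  The persistence metric is Euclidean by
default (cosine is used only in the UMAP visualization, mirroring common
practice).  Jittered spikes falling outside the recording span are
clipped to it (a drop variant is a flag), preserving per-neuron counts.

### The persistence backend

H0 comes from union-find over the sorted edges; H1/H2 from persistent
cohomology: coboundary columns processed in decreasing filtration order
(ties by increasing combinatorial index) with clearing and the
emergent-pair shortcut, the pivot being the earliest cofacet in the
filtration.  The default cutoff is the enclosing radius
min_i max_j d(i, j), where the complex cones off and all finite bars are
exact; anything still alive is truncated there and flagged.  The
implementation is numba-jitted; its cost grows ~n⁴ for H2, so the
package defaults to the standard 1200-point clouds but the test suite
and the acceptance script run **300-point clouds for simulated modules
and 400-point clouds for toy tori** (a 1200-point torus takes ~12
minutes on one core).  At 300 points the self-referenced Γ of the
oscillation-modulated module is 0.81–0.85 / 0.90–0.94 across seeds —
comfortably above the 0.6 torus threshold — and all qualitative
contrasts (oscillations vs none, displacement robustness) are preserved.
A full boundary-matrix reduction oracle verifies every bar on small
random clouds.

## Scoring simulated experiments

Self-mode Γ answers "does this barcode look like *a* torus"; it is used
for the headline simulation results and the displacement scan.  The
oscillations-vs-none contrast is sharper under an *external* reference:
both conditions are scored against the data-mode reference of a
designated oscillation-modulated reference run (a synthetic stand-in for
a recorded module with the same spacing).  Under that estimator the
separation is unambiguous (Γ1 ≈ 0.83 ± 0.01 with oscillations versus
0.65 ± 0.03 without, over 5 seeds each), while self-mode means overlap;
the H1/H2 gap tells the two conditions apart in either scoring
(robustly positive ≈ 0.1 with oscillations, ≈ 0 without).

## Timescales and spectra

Γ-versus-perturbation curves are fitted with
s(x) = L/(1 + exp(−k(x − x_c))) + b by least squares; initialization
uses the empirical plateaus and steepest slope, bounds keep x_c inside
the sampled range, and descending data yield k < 0.  The critical
timescale of a jitter sweep is the smaller of the two components'
inflection points.  The behavioral timescale is grid spacing divided by
mean running speed.

Power spectra are FFT periodograms of 1 ms spike-count series,
normalized to unit power over [0.1, 500) Hz; module spectra average over
neurons.  Eta and theta band powers default to [2.5, 5.9) and
[5.9, 11) Hz (configurable per dataset).  Because the oscillator bank's
amplitude law produces a ~1/f² modulation continuum plus a white Poisson
floor, the 4/8 Hz lines are assessed against that two-component
background fitted on flanking bands; in 30-minute simulated modules the
line excesses are ≈ +9% (eta) and +13% (theta), and vanish without
oscillations.

Ratemaps are smoothed spike-count maps divided by smoothed occupancy
(3 cm bins, 5 cm smoothing, 2.5 cm/s speed filter).  The grid score is
the classic annulus statistic of the spatial autocorrelogram —
min(correlation at 60°, 120°) − max(at 30°, 90°, 150°) on an annulus
from the first radial trough to 1.25× the first hexagonal peak — and
separates hexagonal (score > 0.5) from square (score < 0) lattices on
simulated cells.

## Known limitations

- The Rips backend's H2 cost restricts routine use to ≲500-point clouds
  on one core; larger clouds work but take minutes (threshold arguments
  help when the interesting features die early).
- The i.i.d.-sampling Γ1 ceiling (~0.8) discussed above means absolute
  Γ values should be compared within a sampling scheme, not across.
- Simulated neurons are independent Poisson: no refractoriness, phase
  precession, head-direction tuning, or spike-ordering structure, so
  conclusions about those mechanisms are out of reach by design.
- The reference value 0.5884 sometimes quoted for this oscillator
  recipe's normalization constant is not what the recipe itself yields
  (the faithful 36 s / 1 ms computation gives 2.12 with the sin
  convention and 2.35 with cos); the package therefore always calibrates
  the constant numerically, which is the property the constant exists to
  guarantee.  Simulation behavior is unaffected because the modulation
  depends only on the calibrated product.
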
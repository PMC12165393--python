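# gridtorus

**How torus-like is a neural population's activity manifold — and which
temporal features of spiking make it so?**

Grid cells in the medial entorhinal cortex fire on hexagonal lattices of
spatial fields, and persistent homology applied to their joint activity
reveals a toroidal manifold: barcodes with one long H0 bar, two long H1
bars (the torus' two circles) and one long H2 bar (its cavity).  This
package is for computational neuroscientists who want to go beyond the
binary "torus / no torus" call: it provides a continuous **degree of
toroidality**, a fully specified Poisson grid-cell simulator with
oscillatory rate modulation, the spike-train → barcode pipeline, and the
jittering/spectral analyses that probe *why* the topology is there.

## The measure

For a barcode τ_d (homology dimension d), define the internal spread
u(τ) = max over bar pairs ‖p − p′‖∞ with
‖p − q‖∞ = max(|birth_p − birth_q|, |death_p − death_q|).  The
normalized bottleneck distance and the degree of toroidality are

    d̂_B(τ, τ′) = d_B( τ/u(τ), τ′/u(τ′) ) ∈ [0, 1]
    Γ_d        = 1 − d̂_B(τ_d, τ_d^ref),   d ∈ {1, 2}

where d_B is the bottleneck distance (min over matchings of the max
sup-norm cost, diagonal allowed) and τ^ref is an idealized torus
reference built from the barcode itself: keep the two longest H1 bars
and the longest H2 bar, shrink every other bar to the minimum bar length
of its dimension ("data" mode; a "self" mode additionally equalizes the
two H1 bars).  Γ = (Γ1, Γ2) ranges from 0 (nothing torus-like) to 1
(the idealized reference); in practice both components above ~0.6
correspond to barcodes classified as toroidal.

The simulator draws Poisson spikes with rate

    λ_i(r, t) = [ (λ0 + Σ_k G(|r − r_ik|)) · (c1 + c2 Σ_μ A(ω_μ) cos 2πω_μ t) ]_+

— truncated-Gaussian fields on a randomly shifted hexagonal lattice,
multiplied by a bank of 200 oscillators with a 1/√ω amplitude law and
boosted eta (4 Hz) and theta (8 Hz) lines; c2 is calibrated so the
modulation is rate-neutral.  See `docs/methods.md` for every formula,
default and numerical choice.

## Worked example

```python
import numpy as np
from gridtorus import (Torus3DParams, sample_torus_3d, add_gaussian_noise,
                       rips_persistence, make_reference, toroidality, h1h2_gap)

pts = sample_torus_3d(400, Torus3DParams(a=5, c=10), seed=7)
bset = rips_persistence(pts, maxdim=2)
print("H1 bars:", len(bset.h1), "longest three:",
      np.round(np.sort(bset.h1.lengths)[::-1][:3], 2))
print("H2 bars:", len(bset.h2), "longest two: ",
      np.round(np.sort(bset.h2.lengths)[::-1][:2], 2))

ref = make_reference(bset, "data")
score = toroidality(bset, ref)
print(f"Gamma = ({score.gamma1:.3f}, {score.gamma2:.3f})   "
      f"H1/H2 gap = {h1h2_gap(bset):.2f}")

noisy = add_gaussian_noise(pts, delta=2.0, seed=8)
nscore = toroidality(rips_persistence(noisy, maxdim=2), ref)
print(f"Gamma after noise delta=2: ({nscore.gamma1:.3f}, {nscore.gamma2:.3f})")
```

prints

```
H1 bars: 109 longest three: [6.69 5.69 3.59]
H2 bars: 54 longest two:  [2.15 0.58]
Gamma = (0.764, 0.856)   H1/H2 gap = 1.69
Gamma after noise delta=2: (0.792, 0.469)
```

The clean sample shows the torus signature — two dominant H1 bars (6.7
and 5.7) well separated from the third (3.6), one dominant H2 bar, and a
positive H1/H2 gap (the loops outlive the cavity's birth).  Both Γ
components sit far above the 0.6 threshold; coordinate noise of scale
2 destroys the cavity first, collapsing Γ2 to 0.47 while the loops
momentarily persist.

The same works end to end from spike trains:

```bash
gridtorus simulate --out run/ --seed 1            # 75 Poisson grid cells, 30 min
gridtorus tda --spikes run/spikes.csv --out tda/  # smooth → PCA-6 → downsample → Rips
gridtorus toroidality --barcodes tda/barcodes.csv --reference-mode self
```

Other subcommands: `noise-sweep`, `jitter-sweep`, `psd`, `gridscore`,
and `sweep --kind displacement|frequency|gain|subsample`.

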
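# Methods

## Model

kdentropy estimates the differential entropy S = −R ∫ p ln p dx of a
one-dimensional observable from samples, with R the molar gas constant, so S
is in J/(mol K). The density p is a Gaussian KDE evaluated on a uniform grid:

1. **Binning.** The samples (optionally carrying per-frame weights) are
   accumulated into `r` equal bins; `r` is a power of two. Bins are half-open
   with the final bin closed; a value exactly on an interior edge goes to the
   right-hand bin (a deterministic tie-break). For non-periodic data the grid
   covers the sample range padded by 10% per side; all-identical samples are
   rejected because no density scale exists.
2. **Bandwidth.** The squared kernel bandwidth t (on the grid mapped to the
   unit interval) solves the improved Sheather–Jones fixed point
   `t = (2 N √π ‖p̂_t''‖²)^(−2/5)`, where the curvature functional is estimated
   through a seven-stage recursion over density-derivative functionals built
   from the type-II DCT coefficients of the bin frequencies. The root is
   bracketed on a 400-point log scan of (1e−12, 0.1] and polished with Brent's
   method to xtol 1e−14. If no sign change exists (featureless data — e.g. a
   near-uniform histogram carries no curvature information), the scan point
   minimising |residual| is used and the result is flagged `converged=False`.
3. **Smoothing.** DCT coefficient k is attenuated by `exp(−k²π²t/2)` and the
   transform inverted — the exact Gaussian convolution under reflective
   boundary conditions, O(r log r). Negative round-off values are clipped and
   the density renormalised so its Riemann sum is exactly 1.
4. **Integration.** −R Σ p ln p by composite Simpson (default) on the uniform
   grid, with 0·ln 0 ≡ 0. A trapezoid rule is kept for cross-checking, and a
   midpoint (plain Riemann) rule exists for periodic windows, where it is both
   spectrally accurate and exactly invariant under circular shifts of the
   grid — Simpson's even-interval end correction is not.

A direct-sum evaluator (`direct_sum_density`) computes the same estimate as an
explicit sum of Gaussians in O(n·r). It exists as an independent cross-check
of the spectral path; with `boundary="reflect"` it adds each kernel's first
mirror images and then agrees with the DCT evaluation to ~1e−15 away from the
grid edges.

## Weighted data

Weights enter the histogram directly and are normalised away there (they may
arrive unnormalised). Wherever a sample count N is needed — chiefly the
bandwidth fixed point — the Kish effective sample size (Σw)²/Σw² stands in,
the standard surrogate for weighted KDEs. Unweighted data reduce to
n_eff = N exactly.

## Resolution selection

`auto` resolution for generic data uses the Rice rule `⌈2 n^(1/3)⌉` rounded up
to the next power of two and clamped to [2⁵, 2¹³]; Sturges and square-root
rules are available behind the same flag. Dihedral data use a dedicated
schedule: 4096 bins for n ≥ 10⁴ frames, halving each time the frame count
drops by roughly a factor of four, with a floor of 512 — high resolution when
the data can support it, less when they cannot. Explicit integer requests
that are not powers of two are rounded up with a logged notice at the
pipeline entry points, and rejected in the low-level selector.

## Periodic (dihedral) pipeline

Angles are wrapped to [−180°, 180°) (180.0 maps to −180.0; trajectory tools
emit it occasionally). Periodicity is honoured in three places:

* **Bandwidth** comes from a periodic variant of the ISJ selector: the
  derivative functionals on a circle depend only on the DFT power spectrum
  |c_m|² of the one-period histogram, which maps onto the same recursion by
  placing 2|c_m| at even cosine wavenumber 2m. Because the spectrum is
  phase-blind, the selected bandwidth is exactly invariant under circular
  rotations of the data — a reflective DCT on the replicated histogram is
  not (its phase sensitivity perturbs the bandwidth by a few percent and the
  entropy by ~1e−2 J/(mol K) under a 90° rotation).
* **Density** is smoothed on a triple-replicated grid: every sample also
  appears at ±360°, the KDE is evaluated on [−540°, 540°) with 3r bins, and
  only the central period is kept and renormalised. The reflective boundary
  then sits a full period away from the retained window, so its influence is
  exp(−(360°)²/2t) — zero in practice. The bandwidth fixed point sees the
  *original* effective frame count, so replication does not shrink the kernel.
* **Entropy** is integrated over the central window with the angle in
  radians (midpoint rule). The radian convention fixes the additive constant
  of the differential entropy (a degree convention would add
  R ln(180/π) ≈ 33.8 J/(mol K)); entropy *differences* are unaffected either
  way. Uniform angles on the circle give S = R ln 2π ≈ 15.28 J/(mol K).

Per-residue results group the individual dihedral entropies (each computed
independently — they share no state and can run concurrently) and report
their sum as the residue's combined flexibility; that scalar is what the PDB
B-factor writer projects onto structures, clamped to the fixed-width field
range [0, 999.99].

## Accelerated-MD reweighting

Boosted frames are reweighted by the truncated Maclaurin expansion of
exp(βΔV): w = Σ_{k≤K} (βΔV)^k/k!, K = 10 by default. The truncation tames the
exponential's noise amplification at the cost of a small systematic
undershoot for large βΔV (the analytic remainder of the series). β is fixed
by the temperature with k_B in kcal/(mol K), matching Amber-family boost
energies; ΔV must be non-negative. Weights are returned unnormalised —
normalisation is owned by the binning stage, so a constant boost cancels
exactly and order 0 reproduces the unweighted analysis bit-identically.

## Synthetic data

The fixtures module generates every input the estimators need: Gaussians and
Gaussian mixtures, uniform draws, von Mises angles, and a boosted-dihedral
fixture emulating an accelerated-MD run — angles drawn (by inverse-CDF
sampling on a 2¹⁶-point circular grid) from a two-well von Mises mixture
tilted by a smooth boost potential ΔV(θ) = A(1 + cos(θ − θ₀))/2, together
with each frame's ΔV. Defaults model a typical torsion: wells at −70° and
+50° with κ = 8, A = 1 kcal/mol at 300 K (βΔV up to ≈ 1.7, a moderate boost),
10⁵ frames where the validation experiments need convergence.

Reference entropies are computed from the analytic densities — closed form
for Gaussian and uniform, adaptive quadrature (tolerance 1e−10) for mixtures
and circular distributions — never through the package's own KDE, so accuracy
tests have an independent oracle.

What the fixtures do *not* emulate: autocorrelation between frames (real
trajectory frames are far from independent, so real data carry fewer
effective samples than their frame count suggests), fat-tailed or multimodal
boost distributions, and correlations between dihedrals. Passing tests
demonstrate estimator correctness on ideal samples, not that a given
trajectory is converged.

## Accuracy

Validated against the closed-form Gaussian entropy over replicate draws, the
pipeline's mean absolute relative error is ≈ 4% at n = 300 and ≈ 1% at
n = 10⁴ (recomputed by `scripts/acceptance.py`). The dominant term at large n
is the smoothing bias ½ ln(1 + t/σ²) of integrating the kernel-smoothed
density — about +1.0% at the ISJ bandwidth for n = 10⁴ — partially offset by
a small negative variance term; coarse auto-resolutions add a few hundredths
of a percent. The bias falls with n through the bandwidth, so the error keeps
shrinking for larger samples. No bias correction is applied: the estimator
reports the entropy of the estimated density, nothing else.

## Known limitations

* 1D only: dihedral correlations (and hence mutual-information corrections)
  are out of scope; summed residue entropies are an upper-bound-style
  approximation to the total.
* The plug-in selector needs curvature: on near-uniform data it falls back to
  an unconverged minimum-|residual| bandwidth (flagged in the result and
  logged); entropies remain accurate because a flat density is insensitive
  to smoothing, but the density itself stays histogram-jagged.
* Differential entropies of sharply peaked distributions are negative; the
  B-factor projection clamps them to 0.00 by field-width necessity.
* The direct-sum evaluator is quadratic and intended for n ≲ 10⁴.
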
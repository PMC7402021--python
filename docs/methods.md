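# Methods

## Signal model

Each tissue microdomain (e.g. a myelinated axon segment) with orientation
u ∈ S² at angle θ to the field direction B̂₀ contributes an effective
frequency shift δω(θ, t) = ω_A(t)·sin²θ relative to a short reference echo
t₀.  ω_A(t) (rad/s) is the *microscopic frequency shift*: the shift the
microdomain would show if it were perpendicular to the field.  It is a
phenomenological, echo-time-dependent index of microscopic susceptibility
anisotropy; no compartmental (myelin-water / axonal-water) decomposition is
attempted.  With sin²θ = 1 − ⟨B̂₀,u⟩² and an orientation density p(u)
(non-negative, antipodally symmetric, unit mass) the voxel-scale signal
shift is the spherical convolution

δE(B̂₀, t) = ∫ exp( i·ω_A(t)·[1 − ⟨B̂₀,u⟩²]·(t−t₀) ) p(u) du.

Assumptions: all microdomains in a voxel share one ω_A(t); the magnitude
decay |δE| < 1 caused by intravoxel dephasing is computed but never used in
fitting — only the phase carries the estimand; noise in the frequency
measurements is i.i.d. Gaussian with equal level across field directions.

## Numerical representation

**Spherical harmonics.**  ODFs are represented by 45 coefficients of the
real, orthonormal, even-degree basis up to degree 8 (degrees ascending,
orders −l…l within degree; built from the complex harmonics with
Condon–Shortley phase, ×√2·(−1)^m real/imaginary parts for m ≠ 0).  The
convention is recorded in a JSON sidecar next to every coefficient volume.

**Quadrature grid.**  `make_antipodal_grid(n_half)` mirrors a deterministic
spherical Fibonacci lattice through the origin.  Uniform weights 4π/N
integrate band-limited functions only to a few percent at N = 500, which is
not good enough to serve as an oracle against the spherical-harmonic route,
so a minimum-norm moment correction adjusts the weights to integrate all
even harmonics exactly up to degree 20 (the largest degree the 250-point
hemisphere supports with positive weights; the achieved degree is stored on
the grid).  Weights remain positive and within ~40% of uniform at N = 500.

**Funk–Hecke route.**  For a zonal kernel K(⟨B̂₀,u⟩) the convolution with a
band-limited density diagonalizes: per-degree coefficients
λ_l = 2π ∫ K(c) P_l(c) dc, computed with fixed Gauss–Legendre quadrature
(2·L + 16 nodes — the integrand is a degree-≤L polynomial times the smooth
oscillatory factor exp(i·a(1−c²)) with |a| ≤ π in all supported regimes).
For band-limited ODFs this route is exact up to quadrature precision; the
grid route differs only through the kernel's small spectral content above
the grid's exactness degree (≲1e-7 at degree 20, |a| ≤ π).

**Watson distributions.**  The synthetic generator's dispersed fibers use
the antipodal Watson density ∝ exp(κ⟨μ,u⟩²).  Its degree-≤8 moments are
computed by adaptive 1D quadrature on the shifted integrand exp(κ(c²−1)),
stable at any concentration; no confluent hypergeometric functions are
involved.  κ = ∞ yields the exact antipodal-delta projection
(p_lm = Y_lm(μ)).  Above the documented cap κ = 20 the truncated density
shows ringing beyond ~6% of its peak and `watson_odf` warns (the low-degree
moments remain exact, so weighting and forward signals are still
meaningful).  The cap was chosen where ringing becomes visually and
numerically substantial while still admitting the coherent-fiber regimes
the phantom needs; a strict 1%-of-peak criterion would already exclude
κ ≈ 5, i.e. ordinary dispersed fibers.

**Orientation weighting and entropy.**  π(B̂₀) = ∫ (1 − ⟨B̂₀,u⟩²) p du uses
only the degree-0/2 coefficients (the kernel is a degree-2 zonal
polynomial): π = (2/3)·mass − (8π/15)·Σ_m p_{2m} Y_{2m}(B̂₀).  The
orientation dispersion entropy is the relative entropy of p with respect to
the uniform density, in nats, by grid quadrature; p·ln p is not
band-limited, so accuracy follows the grid density (≈1e-6 absolute at
n_half = 8000), and mild truncation-induced negative excursions are clipped
at 1e-12 while densities below −5% of peak are rejected outright.

## Estimation

**Frequency-difference mapping.**  y = arg(exp(i(φ_t − φ_t₀)))/(t−t₀), the
phases differenced on the complex circle so any common 2πk offset cancels.
Only odd-numbered echoes enter the analysis (even echoes of a bipolar
readout can differ in signal formation); the first selected echo is the
reference.  Residual large-scale fields are removed by a masked 3D
least-squares polynomial detrend (order 0–4, default 2).  This plays the
role a total-generalized-variation field estimate would play in a scanner
pipeline, with a fully specified and testable formulation; either way the
residual is determined only up to a spatially constant per-(direction,
echo) offset φ, which is the documented contract downstream code relies on.

**Phase-metric fit.**  Per voxel and echo the estimator minimizes
Σ_{B̂₀} D{exp(i·y(t−t₀)), sgn δE(ω)}², D = arccos(Re z₁*z₂), over a finite
interval Ω by a dense deterministic grid scan (721 points) followed by
bounded scalar refinement between the bracketing grid points
(xatol = 1e-10).  Ties are broken toward the smallest |ω|.  The objective
is cheap and one-dimensional but can be multimodal under wrapping, which is
why no gradient descent is used.  Voxels whose orientation weighting is
below 1e-3 for every acquired direction are fitted but flagged
ill-conditioned rather than rejected: with realistic dispersion the data
almost always retain some sensitivity.

**Echo-train wrap tracking.**  The first fitted echo t₁ searches
[−π/t₁, +π/t₁]; echo t_{k+1} searches ω̃(t_k) ± π/t_{k+1}.  The half-width
uses the *absolute* echo time, read literally from the interval rule; a
config switch (`interval_mode="relative"`) uses t_{k+1} − t₀ instead for
sensitivity analysis, since the printed rule is ambiguous on this point.

**Joint offset estimation.**  With ≥ 2 head orientations the per-(position,
echo) offsets are estimated jointly with ω̃ by alternating minimization:
(i) track ω̃ per voxel at fixed offsets; (ii) update each offset toward the
circular mean of the per-voxel phase residuals; (iii) refine each echo's
(φ, ω) jointly by Gauss–Newton (`scipy.optimize.least_squares`) on the
signed wrapped-phase residuals, whose squares equal the phase-metric
objective.  Step (iii) exists because the pure alternation moves at only a
few percent per iteration along the nearly degenerate direction that trades
a common offset against compensating voxel shifts; the joint step converges
there quadratically.  Every step is accepted only if it does not increase
the total error, so the iteration is monotone by construction; it stops
when the decrease falls below 1e-8 rad² or after 100 iterations (neither
threshold is externally prescribed; both are this package's defaults).
Identifiability requires the ROI's ODFs to break the symmetry of the
acquired field directions — a set of voxels all symmetric under the
reflection that swaps the tilted positions leaves one offset direction
unconstrained (see the phantom's oblique class below).

**Noise amplification.**  g = (JᵀJ)⁻¹ with
J_p = D{sgn δE(ω̃+ε), sgn δE(ω̃−ε)}/(2ε), ε = 1e-3 rad/s by default (about
1e-6 of the first-echo search-interval width; a step-halving check in the
tests confirms stability).  Under the noise assumptions
Var(ω̃) ≈ g·σ_y²(t−t₀)², validated by a seeded Monte-Carlo oracle that
refits noisy draws (agreement within a few percent at σ_y(t−t₀) = 0.01
rad).  An optional scan-time-corrected variant multiplies g by the number
of field directions so that duplicating an existing direction leaves it
unchanged; the raw definition is the default because no exact published
normalization formula exists for the corrected display.

## Synthetic phantom

The phantom emulates a multi-orientation gradient-echo study on a small
voxel grid (default 10×10×5 = 500 voxels) split into contiguous blocks of
six tissue classes: coherent fiber parallel to the standard field direction
(Watson κ = 20), coherent perpendicular fiber, dispersed fiber (κ = 5),
50/50 orthogonal crossing, an oblique dispersed fiber at 45° in the tilt
plane, and an isotropic region.  The oblique class is there deliberately:
the other five are all invariant under the reflection that swaps the ±29.9°
head positions, and without a symmetry-breaking class the offset/shift
decomposition is exactly degenerate.  The acquisition matches the reference
geometry: 11 echoes from 4.5 ms at 4.5 ms spacing, odd echoes selected,
head positions rotated about the left–right axis with 59.8° between the
extremes.  Ground-truth curves ramp ω_A/(2π) linearly from 0 at the
reference echo to −3 Hz at the last selected echo in fiber classes and stay
at 0 in the isotropic class — white matter's microscopic shift grows more
negative with echo time in vivo, but no published numeric value exists, so
the default is an illustrative, configurable choice.  Offsets and smooth
polynomial background fields are drawn reproducibly from the phantom seed;
Gaussian noise is added to the frequency values (not the raw phase),
i.i.d. across voxels, positions and echoes.

What the phantom does *not* emulate: k-space/coil effects, geometric
distortion, motion, registration error, spatially varying noise, and ODF
estimation error (ODFs are supplied exactly).  Passing tests therefore
demonstrate correctness of the forward model and inversion, not robustness
to acquisition artifacts.

## Numerical choices and degenerate inputs

* Times are carried in seconds internally; interfaces accept milliseconds
  and convert once.  Output maps are stored in Hz (ω/2π); all computation
  is in rad/s.
* The quadrature density convention: p is a true density (∫p du = 1) and
  the grid weights carry the 4π/N factor, so the plain-average form of the
  discrete ensemble signal is reproduced exactly in the band-limited case
  without a 4π ambiguity.
* sgn(δE) at |δE| < 1e-300 (possible only at isolated ω for strongly
  dispersed ODFs) is treated as 1 rather than propagating NaNs; JᵀJ below
  1e-300 reports g = ∞.
* A single head position with a fully parallel ODF produces a flat
  objective; the fit returns the interval's tie-break value (smallest |ω|)
  and the voxel is flagged.

## Known limitations

* The estimator assumes the supplied ODF is correct; errors in the ODF bias
  ω̃ in a voxel-dependent way that is not modeled.
* Offset estimation needs heterogeneous, symmetry-breaking orientation
  structure in the ROI; it degrades gracefully (slow, then degenerate) as
  the ODF field becomes symmetric with respect to the acquired directions.
* The magnitude decay of δE carries additional information about dispersion
  that is deliberately ignored.
* Problem sizes in the shipped tests (500-voxel phantoms, 400–1000
  Monte-Carlo repetitions, 20 validation voxels) are the package's default
  verification scale, chosen to exercise every claim at comfortable
  statistical margins.
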
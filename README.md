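# msai — microscopic susceptibility anisotropy imaging

The phase of the gradient-echo MR signal in brain white matter depends not
only on the magnetic susceptibility of the tissue microstructure (chiefly
the myelin sheath) but also on how the axons are oriented with respect to
the main magnetic field B₀.  A voxel full of fibers perpendicular to the
field shows a very different frequency shift than the same tissue rotated
parallel to it, so raw frequency-difference maps conflate microstructure
with orientation.  `msai` separates the two: given the per-voxel axon
orientation distribution function (ODF, e.g. from spherical deconvolution of
diffusion MRI) it recovers the **microscopic frequency shift** ω_A(t) — the
shift a single microdomain would exhibit if it were oriented perpendicular
to the field — unconfounded by fiber crossings, orientation dispersion, and
head orientation.

## Model

A microdomain at angle θ to B̂₀ contributes the frequency shift
δω(θ, t) = ω_A(t)·sin²θ relative to a short reference echo t₀, hence the
unit phasor exp(i·ω_A(t)·sin²θ·(t−t₀)).  A voxel with orientation density
p(u) produces the ensemble signal shift

    δE(B̂₀, t) = ∫_{S²} exp( i·ω_A(t)·[1 − ⟨B̂₀, u⟩²]·(t − t₀) ) p(u) du ,

evaluated either by antipodal quadrature (N = 500 directions) or exactly via
the Funk–Hecke theorem in the order-8 real spherical-harmonic basis.  The
estimator inverts this per voxel and echo,

    ω̃_A(t) = argmin_{ω ∈ Ω} Σ_{B̂₀} D{ exp(i·y·(t−t₀)), sgn δE(ω) }² ,

with D{z₁,z₂} = arccos(Re z₁*z₂) the distance between unit phasors and
y(B̂₀, t) the measured frequency shift after frequency-difference mapping.
Phase wrapping is handled by tracking the search interval along the echo
train; unknown global per-(direction, echo) frequency offsets are estimated
jointly over a region of interest (this needs ≥ 2 head orientations); and
noise amplification is quantified by the linearized g-factor g = (JᵀJ)⁻¹,
validated against a Monte-Carlo oracle.  The short-time sensitivity of a
voxel is summarized by the orientation distribution weighting
π(B̂₀) = ∫ (1 − ⟨B̂₀,u⟩²) p(u) du ∈ [0, 1] (0: all fibers parallel to the
field; 1: all perpendicular).

## Worked example

Simulate a two-head-orientation acquisition (11 echoes at 4.5 ms spacing,
odd echoes selected, ±29.9° tilt) on a synthetic phantom with known tissue
classes and injected per-(position, echo) global offsets, then jointly
recover offsets and microscopic shift:

```python
import numpy as np
from msai import (
    PhantomConfig, build_phantom, default_scheme, estimate_offsets,
    g_factor, orientation_weighting, simulate_measurements,
)

scheme = default_scheme(2)                      # up/down head tilt, 59.8 deg apart
config = PhantomConfig(offset_amplitude=1.0, grid_shape=(6, 5, 2), seed=42)
phantom = build_phantom(config, scheme)
data = simulate_measurements(phantom, scheme)   # noise-free forward simulation

offsets, result = estimate_offsets(data, phantom.voxel_odfs, scheme)
print("max offset error (rad/s):",
      f"{np.abs(offsets - phantom.offsets_true).max():.2e}")

for idx, name in enumerate(phantom.class_names):
    v = int(np.flatnonzero(phantom.tissue_labels == idx)[0])
    hz = result.omega_A_hat[v] / (2 * np.pi)
    truth_hz = phantom.truth_curves[name].omega_A / (2 * np.pi)
    w = orientation_weighting(phantom.odf_for_voxel(v), scheme.b0_directions[0])
    g, _ = g_factor(result.omega_A_hat[v, -1], phantom.odf_for_voxel(v),
                    scheme, 0.0495, 0.0045)
    print(f"{name:>13}: pi(B0)={w:.3f}  "
          f"omega_hat(49.5ms)={hz[-1]:+.3f} Hz (truth {truth_hz[-1]:+.3f})  g={g:.0f}")
```

Output:

```
max offset error (rad/s): 1.70e-07
     parallel: pi(B0)=0.281  omega_hat(49.5ms)=-3.000 Hz (truth -3.000)  g=3142
perpendicular: pi(B0)=0.974  omega_hat(49.5ms)=-3.000 Hz (truth -3.000)  g=260
    dispersed: pi(B0)=0.396  omega_hat(49.5ms)=-3.000 Hz (truth -3.000)  g=1599
     crossing: pi(B0)=0.628  omega_hat(49.5ms)=-3.000 Hz (truth -3.000)  g=621
      oblique: pi(B0)=0.838  omega_hat(49.5ms)=-3.000 Hz (truth -3.000)  g=629
    isotropic: pi(B0)=0.667  omega_hat(49.5ms)=+0.000 Hz (truth +0.000)  g=556
```

Every tissue class recovers its ground-truth microscopic shift (−3 Hz at the
last echo in fiber classes, 0 in the isotropic class) to display precision,
and the injected global offsets are recovered to ~1e-7 rad/s.  The g-factor
column shows the orientation-dependent noise amplification: the fiber
parallel to the first field direction is the worst-conditioned voxel, the
perpendicular fiber the best.

A command-line interface mirrors the library:
`msai simulate | fdm | fit | gfactor | weighting | entropy`
(NIfTI volumes, JSON schemes, CSV offset tables; run `msai --help`).

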
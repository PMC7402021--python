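"""Microdomain population forward model for the gradient-echo frequency shift.

A single microdomain (e.g. a myelinated axon segment) at angle θ to the
main magnetic field B̂₀ experiences the effective frequency shift

    δω(θ, t) = ω_A(t) · sin²θ

relative to a reference echo time t₀, where ω_A(t) — the *microscopic
frequency shift* — is the shift the same microdomain would show if it were
perpendicular to the field.  The microscopic signal component is the unit
phasor ``exp(i ω_A(t) sin²θ (t − t₀))``, and a voxel containing an ensemble
of microdomains with orientation density p(u) produces the macroscopic
signal shift

    δE(B̂₀, t) = ∫_{S²} exp(i ω_A(t) [1 − ⟨B̂₀,u⟩²] (t − t₀)) p(u) du .

Two evaluation routes are provided: direct quadrature on a
:class:`~msai.sphere.SphereGrid` and the spherical-harmonic (Funk–Hecke)
route, which is exact for band-limited densities.

Unit conventions: ω_A in rad/s; ``t`` and ``t0`` in seconds inside this
module (interfaces that accept milliseconds convert once at the boundary).
The magnitude |δE| ≤ 1 is computed but deliberately not used in fitting —
only the phase carries the estimand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .odf import ODF
from .sphere import (
    SH_MAX_ORDER,
    SphereGrid,
    funk_hecke_convolve,
    real_sh_basis,
    sh_degrees,
    zonal_kernel_coefficients,
    _gl_nodes_for,
)
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

__all__ = [
    "MicroShiftCurve",
    "micro_frequency_shift",
    "micro_signal_shift",
    "ensemble_signal",
    "ensemble_signal_sh",
    "sh_projection_at",
]


@dataclass(frozen=True)
class MicroShiftCurve:
    """Microscopic frequency shift ω_A(t) sampled at echo times (ms)."""

    echo_times_ms: np.ndarray
    omega_A: np.ndarray  # rad/s, one value per echo

    def __post_init__(self) -> None:
        t = np.asarray(self.echo_times_ms, dtype=float)
        w = np.asarray(self.omega_A, dtype=float)
        if t.ndim != 1 or t.shape != w.shape:
            raise ValueError("echo_times_ms and omega_A must be matching 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(w))):
            raise ValueError("curve values must be finite")
        object.__setattr__(self, "echo_times_ms", t)
        object.__setattr__(self, "omega_A", w)

    def at(self, t_ms: float) -> float:
        """ω_A at echo time ``t_ms`` (must be one of the sampled echoes)."""
        idx = np.flatnonzero(np.isclose(self.echo_times_ms, t_ms, atol=1e-9))
        if idx.size != 1:
            raise KeyError(f"echo time {t_ms} ms is not on the curve")
        return float(self.omega_A[idx[0]])


def micro_frequency_shift(omega_A: float, theta: float) -> float:
    """Effective frequency shift ω_A·sin²θ (rad/s) of one microdomain."""
    return omega_A * np.sin(theta) ** 2


def micro_signal_shift(omega_A: float, theta: float, t: float, t0: float) -> complex:
    """Unit-modulus microscopic signal phasor exp(i ω_A sin²θ (t − t₀))."""
    if t < t0:
        raise ValueError(f"t ({t} s) must be >= t0 ({t0} s)")
    return complex(np.exp(1j * micro_frequency_shift(omega_A, theta) * (t - t0)))


_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_rule(max_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached Gauss–Legendre abscissae and weighted Legendre table."""
    if max_order not in _GL_CACHE:
        nodes, weights = leggauss(_gl_nodes_for(max_order))
        degrees = np.arange(0, max_order + 1, 2)
        legendre = eval_legendre(degrees[:, None], nodes[None, :])  # (L, Q)
        _GL_CACHE[max_order] = (nodes, weights[:, None] * legendre.T)
    return _GL_CACHE[max_order]


def _zonal_phase_coeffs(a: np.ndarray, max_order: int = SH_MAX_ORDER) -> np.ndarray:
    """Funk–Hecke coefficients λ_l(a) of c ↦ exp(i·a·(1 − c²)), vectorized.

    Shape: (len(a), max_order//2 + 1).  Gauss–Legendre with
    ``2·max_order + 16`` nodes, ample for |a| ≲ π on top of degree-≤8
    Legendre factors.
    """
    nodes, wleg = _gl_rule(max_order)
    a = np.atleast_1d(np.asarray(a, dtype=float))
    phase = np.exp(1j * a[:, None] * (1.0 - nodes[None, :] ** 2))  # (A, Q)
    return 2.0 * np.pi * phase @ wleg  # (A, L)


def sh_projection_at(odf: ODF, b0: np.ndarray) -> np.ndarray:
    """Per-degree sums q_l = Σ_m p_{lm} Y_{lm}(b̂₀), used by the SH route."""
    b0 = np.asarray(b0, dtype=float)
    basis = real_sh_basis(b0[None, :], SH_MAX_ORDER)[0]
    prod = odf.sh_coeffs * basis
    degrees = sh_degrees(SH_MAX_ORDER)
    return np.array(
        [prod[degrees == l].sum() for l in range(0, SH_MAX_ORDER + 1, 2)]
    )


def ensemble_signal_sh(q: np.ndarray, a: np.ndarray) -> np.ndarray:
    """δE for per-degree projections ``q`` over accumulated phases ``a``.

    ``a = ω_A (t − t₀)``; vectorized over ``a``.  Exact for band-limited
    ODFs up to Gauss–Legendre precision of the kernel coefficients.
    """
    lam = _zonal_phase_coeffs(a)
    return lam @ q


def ensemble_signal(
    odf: ODF,
    omega_A: float,
    b0: np.ndarray,
    t: float,
    t0: float,
    grid: SphereGrid | None = None,
    method: str = "sh",
) -> complex:
    """Macroscopic (voxel-scale) signal shift δE(B̂₀, t).

    Parameters
    ----------
    odf : orientation density of the voxel.
    omega_A : microscopic frequency shift at echo time ``t`` (rad/s).
    b0 : unit field direction.
    t, t0 : echo and reference times in **seconds**, ``t >= t0``.
    grid : quadrature grid (required for ``method="quadrature"``).
    method : ``"sh"`` (Funk–Hecke, default) or ``"quadrature"``
        (weighted sum ``Σ_j w_j exp(i ω_A [1 − ⟨b̂₀,u_j⟩²](t−t₀)) p(u_j)``;
        the weights carry the 4π/N factor since p is a true density).
    """
    b0 = np.asarray(b0, dtype=float)
    if b0.shape != (3,) or abs(np.linalg.norm(b0) - 1.0) > 1e-10:
        raise ValueError("b0 must be a unit 3-vector")
    if t < t0:
        raise ValueError(f"t ({t} s) must be >= t0 ({t0} s)")
    a = omega_A * (t - t0)
    if method == "sh":
        kernel_coeffs = zonal_kernel_coefficients(
            lambda c: np.exp(1j * a * (1.0 - c * c)), SH_MAX_ORDER
        )
        return funk_hecke_convolve(odf, kernel_coeffs, b0)
    if method == "quadrature":
        if grid is None:
            raise ValueError("quadrature method requires a SphereGrid")
        cos2 = (grid.directions @ b0) ** 2
        integrand = np.exp(1j * a * (1.0 - cos2)) * odf.density(grid.directions)
        return complex(grid.integrate(integrand))
    raise ValueError(f"unknown method {method!r}; use 'sh' or 'quadrature'")
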
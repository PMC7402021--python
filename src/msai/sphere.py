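"""Unit-sphere sampling, real spherical harmonics, and zonal convolution.

This module provides the numerical backbone for orientation-resolved
gradient-echo signal modeling: an antipodally symmetric quadrature grid on
S², the real, orthonormal, even-order spherical-harmonic (SH) basis used to
represent axon orientation distributions, and the Funk–Hecke route for
convolving a zonal kernel K(⟨b̂₀, u⟩) with an SH-represented density.

Conventions (fixed project-wide)
--------------------------------
* SH basis: real, orthonormal, even orders only.  For degree ``l`` and
  order ``m`` the basis function is built from the complex harmonic
  ``Y_l^m(θ, φ)`` (Condon–Shortley phase included) as

  - ``m < 0``:  ``√2 · (−1)^m · Im(Y_l^{|m|})``
  - ``m = 0``:  ``Y_l^0``
  - ``m > 0``:  ``√2 · (−1)^m · Re(Y_l^m)``

* Coefficient ordering: degrees ascending (0, 2, 4, …), orders −l…l within
  each degree.  For maximum degree 8 this yields 45 coefficients.
* Funk–Hecke coefficients: ``λ_l = 2π ∫_{−1}^{1} K(c) P_l(c) dc`` so that
  ``∫ K(⟨b̂₀,u⟩) p(u) du = Σ_l λ_l Σ_m p_{lm} Y_{lm}(b̂₀)`` for any
  band-limited density ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "SphereGrid",
    "make_antipodal_grid",
    "real_sh_basis",
    "n_sh_coeffs",
    "sh_degrees",
    "zonal_kernel_coefficients",
    "funk_hecke_convolve",
]

#: Default maximum SH degree used throughout the package.
SH_MAX_ORDER = 8

#: Gauss–Legendre node count for zonal kernel coefficients, per max degree L.
def _gl_nodes_for(max_order: int) -> int:
    return 2 * max_order + 16


def n_sh_coeffs(max_order: int) -> int:
    """Number of even-degree real SH coefficients up to ``max_order``."""
    if max_order % 2:
        raise ValueError(f"max_order must be even, got {max_order}")
    return (max_order // 2 + 1) * (max_order + 1)


def sh_degrees(max_order: int) -> np.ndarray:
    """Degree ``l`` of each coefficient in the documented ordering."""
    return np.concatenate(
        [np.full(2 * l + 1, l, dtype=int) for l in range(0, max_order + 1, 2)]
    )


@dataclass(frozen=True)
class SphereGrid:
    """Antipodally paired unit directions with quadrature weights.

    ``directions`` has shape (N, 3) with the first N/2 rows on the upper
    hemisphere and rows ``j`` and ``j + N/2`` forming exact (u, −u) pairs;
    ``weights`` (steradian) are positive and sum to 4π.
    """

    directions: np.ndarray
    weights: np.ndarray
    #: largest even SH degree the grid integrates exactly (moment-fitted).
    exact_degree: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] % 2:
            raise ValueError("directions must be (N, 3) with N even")
        if w.shape != (d.shape[0],):
            raise ValueError("weights must be one per direction")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("directions must be unit-norm within 1e-12")
        n_half = d.shape[0] // 2
        if not np.array_equal(d[:n_half], -d[n_half:]):
            raise ValueError("directions must come in exact (u, -u) pairs")
        if not np.array_equal(w[:n_half], w[n_half:]):
            raise ValueError("antipodal pairs must share weights")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 4 * np.pi) > 1e-10:
            raise ValueError("weights must sum to 4*pi within 1e-10")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "weights", w)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def integrate(self, values: np.ndarray) -> float | complex:
        """Quadrature sum ``Σ_j w_j f(u_j)`` over the grid."""
        return np.tensordot(np.asarray(values), self.weights, axes=([-1], [0]))


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic spherical Fibonacci lattice on the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_antipodal_grid(n_half: int) -> SphereGrid:
    """Build an antipodally symmetric quadrature grid with 2·``n_half`` points.

    The point set is a spherical Fibonacci lattice on the upper hemisphere
    mirrored through the origin.  Equal weights 4π/N alone integrate
    band-limited functions only to a few-percent accuracy, so a minimum-norm
    moment correction is applied: the weights are adjusted (staying positive
    and near-uniform for ``n_half ≥ 250``) such that all even real spherical
    harmonics up to the largest supportable even degree — 20 when the grid is
    dense enough — integrate exactly.  The achieved degree is recorded in
    ``exact_degree``.
    """
    if not isinstance(n_half, (int, np.integer)) or n_half < 4:
        raise ValueError(f"n_half must be an integer >= 4, got {n_half!r}")
    half = _fibonacci_hemisphere(int(n_half))
    directions = np.vstack([half, -half])
    n = directions.shape[0]
    w_uniform = np.full(n, 4.0 * np.pi / n)

    # Moment-fit on the hemisphere (antipodal pairing shares weights and
    # cancels odd degrees automatically).  Reduce the target degree until the
    # system is well-posed and the corrected weights stay positive.
    weights = w_uniform
    exact_degree = 0
    for target in range(20, -1, -2):
        if n_sh_coeffs(target) > n_half:
            continue
        basis_h = real_sh_basis(half, target)  # (n_half, K)
        moments = np.zeros(basis_h.shape[1])
        moments[0] = 2.0 * np.sqrt(np.pi)  # ∫ Y00 du over S²
        w_half = np.full(n_half, 4.0 * np.pi / n)
        # each hemisphere weight counts twice (its mirror shares it)
        residual = moments - 2.0 * basis_h.T @ w_half
        try:  # minimum-norm correction via the normal equations

            correction = basis_h @ np.linalg.solve(
                2.0 * basis_h.T @ basis_h, residual
            )
        except np.linalg.LinAlgError:
            continue
        cand = w_half + correction
        if np.all(cand > 0):
            weights = np.concatenate([cand, cand])
            exact_degree = target
            break
    return SphereGrid(directions=directions, weights=weights, exact_degree=exact_degree)


def real_sh_basis(directions: np.ndarray, max_order: int = SH_MAX_ORDER) -> np.ndarray:
    """Evaluate the real, orthonormal, even-degree SH basis.

    Parameters
    ----------
    directions : (N, 3) array of unit vectors.
    max_order : even maximum degree, ≤ 20.

    Returns
    -------
    (N, K) matrix with K = ``n_sh_coeffs(max_order)`` columns in the
    documented ordering (degrees ascending, orders −l…l within degree).
    """
    if max_order % 2 or max_order < 0 or max_order > 20:
        raise ValueError(f"max_order must be even and in 0..20, got {max_order}")
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-10):
        raise ValueError("directions must be unit-norm")
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols = []
    for l in range(0, max_order + 1, 2):
        # sph_harm_y(l, m, theta, phi): theta polar, phi azimuth
        ylm = {m: sph_harm_y(l, m, theta, phi) for m in range(0, l + 1)}
        for m in range(-l, l + 1):
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm[-m].imag)
            elif m == 0:
                cols.append(ylm[0].real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * ylm[m].real)
    return np.column_stack(cols)


def zonal_kernel_coefficients(
    kernel: Callable[[np.ndarray], np.ndarray],
    max_order: int = SH_MAX_ORDER,
    n_nodes: int | None = None,
) -> np.ndarray:
    """Legendre (Funk–Hecke) coefficients ``λ_l`` of a zonal kernel.

    ``λ_l = 2π ∫_{−1}^{1} kernel(c) P_l(c) dc`` computed with fixed-order
    Gauss–Legendre quadrature (default ``2·max_order + 16`` nodes).  Returned
    as a complex array over even degrees 0, 2, …, ``max_order``.
    """
    if max_order % 2:
        raise ValueError(f"max_order must be even, got {max_order}")
    if n_nodes is None:
        n_nodes = _gl_nodes_for(max_order)
    nodes, gl_weights = leggauss(n_nodes)
    values = np.asarray(kernel(nodes), dtype=complex)
    if values.shape != nodes.shape:
        values = np.broadcast_to(values, nodes.shape).astype(complex)
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("kernel returned non-finite values on [-1, 1]")
    degrees = np.arange(0, max_order + 1, 2)
    legendre = eval_legendre(degrees[:, None], nodes[None, :])
    return 2.0 * np.pi * legendre @ (gl_weights * values)


def funk_hecke_convolve(
    odf, kernel_coeffs: np.ndarray, b0: np.ndarray
) -> complex:
    """Evaluate ``∫ kernel(⟨b̂₀, u⟩) p(u) du`` via the Funk–Hecke theorem.

    ``odf`` may be an :class:`msai.odf.ODF` or a raw coefficient vector in
    the documented ordering.  ``kernel_coeffs`` are the per-even-degree
    ``λ_l`` from :func:`zonal_kernel_coefficients` and must cover at least
    the ODF's degrees.
    """
    coeffs = np.asarray(getattr(odf, "sh_coeffs", odf), dtype=float)
    lam = np.asarray(kernel_coeffs)
    odf_order = _order_from_ncoeffs(coeffs.shape[0])
    kernel_order = 2 * (lam.shape[0] - 1)
    if kernel_order < odf_order:
        raise ValueError(
            f"kernel coefficients cover degree {kernel_order} but the ODF "
            f"has degree {odf_order}"
        )
    b0 = np.asarray(b0, dtype=float)
    basis = real_sh_basis(b0[None, :], odf_order)[0]
    per_degree = lam[sh_degrees(odf_order) // 2]
    return complex(np.sum(per_degree * coeffs * basis))


def _order_from_ncoeffs(n: int) -> int:
    for order in range(0, 22, 2):
        if n_sh_coeffs(order) == n:
            return order
    raise ValueError(f"{n} is not a valid even-degree SH coefficient count")
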
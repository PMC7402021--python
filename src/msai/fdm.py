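"""Frequency-difference mapping (FDM) and residual background removal.

FDM subtracts the phase at a short reference echo from later echoes,
suppressing time-invariant frequency components and hence long-range field
inhomogeneity.  What remains is the frequency-shift measurement
``y(B̂₀, t)`` in rad/s per voxel, per field direction, per echo — known only
up to a spatially constant, per-(direction, echo) offset φ once the
residual large-scale field has been removed.

Background removal here is a masked 3D polynomial detrend (default order 2):
it plays the role of slowly-varying field removal with a fully specified,
testable formulation, and preserves exactly the documented contract that the
residual is determined only up to the global additive constant φ (the
constant polynomial term is absorbed into the background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "FrequencyShiftData",
    "frequency_difference",
    "remove_background",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Field directions per head position, echo times, and echo selection.

    ``b0_directions``: (P, 3) unit vectors, one per head position, in the
    image/world frame.  ``echo_times_ms``: strictly increasing echo train.
    ``echo_mask``: which echoes enter the analysis (default: odd-numbered
    echoes only, since even echoes of a bipolar readout may differ in signal
    formation).  ``reference_time_ms`` must be the first selected echo.
    """

    b0_directions: np.ndarray
    echo_times_ms: np.ndarray
    reference_time_ms: float
    echo_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        b0 = np.atleast_2d(np.asarray(self.b0_directions, dtype=float))
        t = np.asarray(self.echo_times_ms, dtype=float)
        if b0.ndim != 2 or b0.shape[1] != 3:
            raise ValueError("b0_directions must be (P, 3)")
        norms = np.linalg.norm(b0, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("b0 directions must be unit-norm within 1e-10")
        if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        mask = self.echo_mask
        if mask is None:
            mask = (np.arange(t.size) % 2) == 0  # odd-numbered echoes (1-based)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != t.shape or not mask.any():
            raise ValueError("echo_mask must match echo_times_ms and select >= 1")
        selected = t[mask]
        if abs(selected[0] - self.reference_time_ms) > 1e-9:
            raise ValueError(
                f"reference_time_ms ({self.reference_time_ms}) must equal the "
                f"first selected echo time ({selected[0]})"
            )
        object.__setattr__(self, "b0_directions", b0)
        object.__setattr__(self, "echo_times_ms", t)
        object.__setattr__(self, "echo_mask", mask)

    @property
    def n_positions(self) -> int:
        return self.b0_directions.shape[0]

    @property
    def selected_echo_times_ms(self) -> np.ndarray:
        """Echo times passing the mask (includes the reference echo)."""
        return self.echo_times_ms[self.echo_mask]

    @property
    def fitted_echo_times_ms(self) -> np.ndarray:
        """Selected echoes strictly after the reference (where y is defined)."""
        sel = self.selected_echo_times_ms
        return sel[sel > self.reference_time_ms + 1e-9]

    @property
    def n_fitted_echoes(self) -> int:
        return self.fitted_echo_times_ms.size


@dataclass(frozen=True)
class FrequencyShiftData:
    """Frequency-shift measurements y (rad/s), voxel × position × echo.

    ``values`` has shape (V, P, E) with E the scheme's fitted echoes (the
    selected echoes after the reference).  ``noise_sigma`` optionally records
    the per-measurement Gaussian noise level in rad/s.
    """

    values: np.ndarray
    scheme: AcquisitionScheme
    noise_sigma: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (self.scheme.n_positions, self.scheme.n_fitted_echoes)
        if v.ndim != 3 or v.shape[1:] != expected:
            raise ValueError(
                f"values must be (V, {expected[0]}, {expected[1]}), got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("frequency-shift values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def frequency_difference(
    phase_t: np.ndarray, phase_t0: np.ndarray, t_ms: float, t0_ms: float
) -> np.ndarray:
    """Frequency shift (rad/s) from two phase images, wrap-consistently.

    Phases are differenced on the complex circle — via the argument of the
    complex ratio — so any common 2πk offset cancels exactly:
    ``y = arg(exp(i(φ_t − φ_t0))) / (t − t0)`` with the time step in seconds.
    """
    if t_ms <= t0_ms:
        raise ValueError(f"t ({t_ms} ms) must be > t0 ({t0_ms} ms)")
    phase_t = np.asarray(phase_t, dtype=float)
    phase_t0 = np.asarray(phase_t0, dtype=float)
    dphi = np.angle(np.exp(1j * (phase_t - phase_t0)))
    return dphi / ((t_ms - t0_ms) * 1e-3)


def _poly_design(shape: tuple[int, ...], order: int) -> np.ndarray:
    """3D polynomial design matrix over all voxels, coords scaled to [−1, 1]."""
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    coords = [g.ravel() for g in grids]
    cols = [np.ones(coords[0].size)]
    for degree in range(1, order + 1):
        for combo in combinations_with_replacement(range(len(shape)), degree):
            term = np.ones(coords[0].size)
            for axis in combo:
                term = term * coords[axis]
            cols.append(term)
    return np.column_stack(cols)


def remove_background(
    frequency_map: np.ndarray, mask: np.ndarray, poly_order: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a masked least-squares 3D polynomial background field.

    Returns ``(residual, background)``.  The constant term belongs to the
    background, so the residual is known only up to a spatially constant
    offset φ — that constant is estimated jointly with the microscopic shift
    downstream (see :func:`msai.fit.estimate_offsets`).
    """
    if not (0 <= poly_order <= 4):
        raise ValueError(f"poly_order must be in 0..4, got {poly_order}")
    vol = np.asarray(frequency_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask shape must match the frequency map")
    design = _poly_design(vol.shape, poly_order)
    flat_mask = mask.ravel()
    n_terms = design.shape[1]
    if flat_mask.sum() < n_terms:
        raise ValueError(
            f"mask has {flat_mask.sum()} voxels but the order-{poly_order} "
            f"fit needs at least {n_terms}"
        )
    coeffs, *_ = np.linalg.lstsq(
        design[flat_mask], vol.ravel()[flat_mask], rcond=None
    )
    background = (design @ coeffs).reshape(vol.shape)
    return vol - background, background
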
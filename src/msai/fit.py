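"""Voxelwise estimation of the microscopic frequency shift.

The estimator inverts the microdomain population model: given frequency
shift measurements ``y(B̂₀, t)`` at one or more field directions and the
voxel's orientation distribution ``p``, it finds

    ω̃_A(t) = argmin_{ω ∈ Ω} Σ_{B̂₀} D{ exp(i·y·(t−t₀)), sgn(δE(ω; B̂₀, t)) }²

where ``D{z₁, z₂} = arccos(Re(z₁* z₂))`` is the distance between unit
phasors and sgn(z) = z/|z|.  Only the phase of δE is used; the magnitude
decay is deliberately ignored.

Because phase wraps, the objective can be multimodal.  Estimation over an
echo train therefore tracks the solution: the first fitted echo searches an
interval centred at 0 with half-width π/t₁, and each later echo t_{k+1}
searches ``[ω̃(t_k) − π/t_{k+1}, ω̃(t_k) + π/t_{k+1}]``, assuming the
microscopic shift evolves smoothly in time.

After background removal each (field direction, echo) measurement carries an
unknown spatially constant frequency offset φ.  With at least two head
orientations, :func:`estimate_offsets` recovers these jointly with the
microscopic shift by alternating minimization over a region of interest.

The optimizer is a deterministic dense grid scan (default 721 points)
followed by bounded local refinement — the objective is cheap,
one-dimensional and possibly multimodal, and determinism aids testing.
Ties are broken toward the smallest |ω|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .fdm import AcquisitionScheme, FrequencyShiftData
from .forward import ensemble_signal_sh, sh_projection_at
from .odf import ODF, orientation_weighting

__all__ = [
    "MicroShiftResult",
    "phase_distance",
    "fit_voxel",
    "track_echo_train",
    "estimate_offsets",
    "ILL_CONDITIONED_WEIGHTING",
]

#: Voxels whose orientation weighting is below this for every acquired field
#: direction are fitted but flagged: the data carry almost no sensitivity to
#: the microscopic shift there.
ILL_CONDITIONED_WEIGHTING = 1e-3

_DEFAULT_N_GRID = 721


@dataclass
class MicroShiftResult:
    """Per-voxel microscopic frequency shift estimates over an echo train.

    ``omega_A_hat`` and ``residual`` have shape (V, E) over fitted echoes;
    ``intervals`` (V, E, 2) are the search bounds actually used (each
    estimate lies inside its interval); ``offsets`` (P, E) are the global
    per-(position, echo) frequency constants in rad/s when estimated;
    ``gfactor`` optionally holds per-voxel noise amplification;
    ``ill_conditioned`` flags voxels with negligible orientation weighting
    for every acquired direction.
    """

    omega_A_hat: np.ndarray
    residual: np.ndarray
    intervals: np.ndarray
    echo_times_ms: np.ndarray
    offsets: np.ndarray | None = None
    gfactor: np.ndarray | None = None
    ill_conditioned: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def phase_distance(z1, z2):
    """Angle in [0, π] between the phases of two nonzero complex numbers."""
    z1 = np.asarray(z1, dtype=complex)
    z2 = np.asarray(z2, dtype=complex)
    m1 = np.abs(z1)
    m2 = np.abs(z2)
    if np.any(m1 == 0) or np.any(m2 == 0):
        raise ValueError("phase_distance is undefined for zero inputs")
    inner = np.real(np.conj(z1 / m1) * (z2 / m2))
    out = np.arccos(np.clip(inner, -1.0, 1.0))
    return float(out) if out.ndim == 0 else out


def _sgn(z: np.ndarray) -> np.ndarray:
    mag = np.abs(z)
    # |δE| can vanish only at isolated ω for strongly dispersed ODFs; treat
    # the phase there as 0 rather than propagating NaNs.
    safe = np.where(mag > 1e-300, mag, 1.0)
    return np.where(mag > 1e-300, z / safe, 1.0 + 0.0j)


def _objective_on(
    omegas: np.ndarray, q: np.ndarray, data_phasors: np.ndarray, dt: float
) -> np.ndarray:
    """Vectorized objective over candidate ω values.

    ``q``: per-position degree projections, shape (P, n_degrees);
    ``data_phasors``: exp(i y (t−t₀)) per position, shape (P,).
    """
    a = np.atleast_1d(omegas) * dt
    delta_e = ensemble_signal_sh(q.T, a)  # (A, P): lam(a) @ q.T
    model = _sgn(delta_e)
    inner = np.real(np.conj(model) * data_phasors[None, :])
    d = np.arccos(np.clip(inner, -1.0, 1.0))
    return np.sum(d * d, axis=1)


def fit_voxel(
    y: np.ndarray,
    odf: ODF,
    b0_directions: np.ndarray,
    t: float,
    t0: float,
    interval: tuple[float, float],
    n_grid: int = _DEFAULT_N_GRID,
) -> tuple[float, float]:
    """Estimate ω_A at a single echo for one voxel.

    Parameters
    ----------
    y : frequency-shift measurement per head position (rad/s).
    odf : the voxel's orientation distribution.
    b0_directions : (P, 3) unit field directions matching ``y``.
    t, t0 : echo and reference time in seconds, ``t > t0``.
    interval : finite search bounds (rad/s).
    n_grid : dense-scan resolution before bounded refinement.

    Returns
    -------
    (omega_A_hat, residual) — the argmin and the objective value there.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    b0s = np.atleast_2d(np.asarray(b0_directions, dtype=float))
    if y.shape[0] != b0s.shape[0] or y.shape[0] < 1:
        raise ValueError("need one measurement per head position")
    lo, hi = float(interval[0]), float(interval[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"interval must be finite and nonempty, got {interval}")
    dt = t - t0
    if dt <= 0:
        raise ValueError("t must be strictly after t0")
    q = np.stack([sh_projection_at(odf, b) for b in b0s])  # (P, L+1)
    return _fit_q(y, q, dt, (lo, hi), n_grid)


def _fit_q(
    y: np.ndarray,
    q: np.ndarray,
    dt: float,
    interval: tuple[float, float],
    n_grid: int,
) -> tuple[float, float]:
    """Core dense-scan + bounded-refinement search at precomputed q."""
    lo, hi = interval
    data_phasors = np.exp(1j * y * dt)
    grid = np.linspace(lo, hi, n_grid)
    obj = _objective_on(grid, q, data_phasors, dt)
    near = np.flatnonzero(obj <= obj.min() + 1e-15)
    j = near[np.argmin(np.abs(grid[near]))]  # tie-break toward smallest |ω|
    best_omega, best_obj = float(grid[j]), float(obj[j])
    # bounded refinement between the neighbouring grid points
    bl = grid[max(j - 1, 0)]
    bh = grid[min(j + 1, n_grid - 1)]
    if bh > bl:
        res = minimize_scalar(
            lambda w: float(_objective_on(np.array([w]), q, data_phasors, dt)[0]),
            bounds=(bl, bh),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= best_obj:
            best_omega, best_obj = float(res.x), float(res.fun)
    return best_omega, best_obj


def track_echo_train(
    y_train: np.ndarray,
    odf: ODF,
    scheme: AcquisitionScheme,
    offsets: np.ndarray | None = None,
    interval_mode: str = "absolute",
    n_grid: int = _DEFAULT_N_GRID,
) -> MicroShiftResult:
    """Track ω̃_A across the echo train for one voxel.

    ``y_train``: (P, E) measurements over fitted echoes.  The first fitted
    echo searches ``[−π/t₁, +π/t₁]`` (t₁ the absolute echo time in seconds;
    ``interval_mode="relative"`` uses t₁ − t₀ instead), later echoes search
    ``ω̃(t_k) ± π/t_{k+1}``.  ``offsets`` (P, E) in rad/s are subtracted
    from the measurements before fitting.
    """
    if interval_mode not in ("absolute", "relative"):
        raise ValueError(f"unknown interval_mode {interval_mode!r}")
    y_train = np.atleast_2d(np.asarray(y_train, dtype=float))
    times_ms = scheme.fitted_echo_times_ms
    if np.any(np.diff(times_ms) <= 0):
        raise ValueError("echo times must be strictly increasing")
    n_echoes = times_ms.size
    if y_train.shape != (scheme.n_positions, n_echoes):
        raise ValueError(
            f"y_train must be ({scheme.n_positions}, {n_echoes}), "
            f"got {y_train.shape}"
        )
    if offsets is not None:
        y_train = y_train - np.asarray(offsets, dtype=float)
    q = np.stack([sh_projection_at(odf, b) for b in scheme.b0_directions])
    omega, resid, intervals = _track_q(y_train, q, scheme, interval_mode, n_grid)
    weightings = [
        orientation_weighting(odf, b) for b in scheme.b0_directions
    ]
    flagged = bool(max(weightings) < ILL_CONDITIONED_WEIGHTING)
    return MicroShiftResult(
        omega_A_hat=omega[None, :],
        residual=resid[None, :],
        intervals=intervals[None, :, :],
        echo_times_ms=times_ms,
        ill_conditioned=np.array([flagged]),
        meta={"interval_mode": interval_mode},
    )


def _track_q(
    y_train: np.ndarray,
    q: np.ndarray,
    scheme: AcquisitionScheme,
    interval_mode: str,
    n_grid: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Echo-train tracking at precomputed per-position projections q."""
    times_ms = scheme.fitted_echo_times_ms
    t0 = scheme.reference_time_ms * 1e-3
    n_echoes = times_ms.size
    omega = np.zeros(n_echoes)
    resid = np.zeros(n_echoes)
    intervals = np.zeros((n_echoes, 2))
    prev = None
    for k, t_ms in enumerate(times_ms):
        t = t_ms * 1e-3
        denom = t if interval_mode == "absolute" else t - t0
        half = np.pi / denom
        center = 0.0 if prev is None else prev
        intervals[k] = (center - half, center + half)
        omega[k], resid[k] = _fit_q(
            y_train[:, k], q, t - t0, tuple(intervals[k]), n_grid
        )
        prev = omega[k]
    return omega, resid, intervals


def _model_phasors_q(q: np.ndarray, omega: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """sgn(δE) at fitted estimates for projections q (P, L+1): shape (P, E)."""
    out = np.empty((q.shape[0], dts.size), dtype=complex)
    for p in range(q.shape[0]):
        out[p] = _sgn(ensemble_signal_sh(q[p], omega * dts))
    return out


def _total_objective(
    values: np.ndarray,
    offsets: np.ndarray,
    models: np.ndarray,
    dts: np.ndarray,
) -> float:
    """Σ over voxels, positions, echoes of D² at fixed models and offsets."""
    data = np.exp(1j * (values - offsets[None, :, :]) * dts[None, None, :])
    inner = np.real(np.conj(models) * data)
    d = np.arccos(np.clip(inner, -1.0, 1.0))
    return float(np.sum(d * d))


def estimate_offsets(
    data: FrequencyShiftData,
    odfs: list[ODF],
    scheme: AcquisitionScheme,
    roi: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    interval_mode: str = "absolute",
    n_grid: int = _DEFAULT_N_GRID,
) -> tuple[np.ndarray, MicroShiftResult]:
    """Jointly estimate global offsets φ and the microscopic shift field.

    Alternating minimization: (i) with offsets fixed, track ω̃_A per voxel;
    (ii) with ω̃_A fixed, update each φ(position, echo) toward the circular
    mean of the per-voxel phase residuals, accepting the update only if it
    does not increase that (position, echo)'s objective — so the total error
    is non-increasing.  Stops when the decrease falls below ``tol`` (rad²)
    or after ``max_iter`` iterations.  Requires at least 2 head positions.
    """
    if scheme.n_positions < 2:
        raise ValueError(
            "joint offset estimation requires at least 2 head orientations"
        )
    values = data.values
    n_vox = values.shape[0]
    if len(odfs) != n_vox:
        raise ValueError("need one ODF per voxel")
    if roi is None:
        roi = np.ones(n_vox, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("roi must contain at least one voxel")
    roi_idx = np.flatnonzero(roi)
    t0 = scheme.reference_time_ms * 1e-3
    dts = scheme.fitted_echo_times_ms * 1e-3 - t0
    n_echoes = dts.size
    offsets = np.zeros((scheme.n_positions, n_echoes))

    omega = np.zeros((n_vox, n_echoes))
    resid = np.zeros((n_vox, n_echoes))
    intervals = np.zeros((n_vox, n_echoes, 2))
    flagged = np.zeros(n_vox, dtype=bool)
    models = np.zeros((roi_idx.size, scheme.n_positions, n_echoes), dtype=complex)

    # per-voxel degree projections, computed once (ODF objects often repeat)
    q_cache: dict[int, np.ndarray] = {}
    w_cache: dict[int, bool] = {}
    q_rows = []
    weighting_ok = np.empty(roi_idx.size, dtype=bool)
    for row, v in enumerate(roi_idx):
        key = id(odfs[v])
        if key not in q_cache:
            q_cache[key] = np.stack(
                [sh_projection_at(odfs[v], b) for b in scheme.b0_directions]
            )
            w_cache[key] = max(
                orientation_weighting(odfs[v], b) for b in scheme.b0_directions
            ) >= ILL_CONDITIONED_WEIGHTING
        q_rows.append(q_cache[key])
        weighting_ok[row] = w_cache[key]
    q_all = np.stack(q_rows)

    prev_total = np.inf
    total = np.inf
    for _ in range(max_iter):
        # (i) voxelwise tracking at current offsets, guarded per voxel
        for row, v in enumerate(roi_idx):
            om, rs, iv = _track_q(
                values[v] - offsets, q_all[row], scheme, interval_mode, n_grid
            )
            cand_models = _model_phasors_q(q_all[row], om, dts)
            if np.isfinite(prev_total):
                old_obj = _total_objective(
                    values[v][None], offsets, models[row][None], dts
                )
                new_obj = _total_objective(
                    values[v][None], offsets, cand_models[None], dts
                )
                if new_obj > old_obj:
                    continue  # keep previous estimate for this voxel
            omega[v] = om
            resid[v] = rs
            intervals[v] = iv
            flagged[v] = not weighting_ok[row]
            models[row] = cand_models

        # (ii) offset update: circular mean of per-voxel phase residuals,
        # accepted only when it does not increase the objective
        vals_roi = values[roi_idx]
        for p in range(scheme.n_positions):
            for e in range(n_echoes):
                data_ph = np.exp(1j * vals_roi[:, p, e] * dts[e])
                residual_ph = data_ph * np.conj(models[:, p, e])
                mean_dir = residual_ph.mean()
                if abs(mean_dir) < 1e-300:
                    continue
                cand = float(np.angle(mean_dir) / dts[e])
                cur = _pe_objective(vals_roi[:, p, e], offsets[p, e],
                                    models[:, p, e], dts[e])
                new = _pe_objective(vals_roi[:, p, e], cand,
                                    models[:, p, e], dts[e])
                if new <= cur:
                    offsets[p, e] = cand

        # (iii) joint per-echo Gauss–Newton refinement of (φ, ω), accepted
        # only when it lowers the total error (it targets the slow, nearly
        # degenerate common-offset direction the alternation cannot move)
        for e in range(n_echoes):
            phi_new, omega_new = _refine_echo(
                vals_roi[:, :, e], q_all, float(dts[e]),
                offsets[:, e].copy(), omega[roi_idx, e].copy(),
                intervals[roi_idx, e, :],
            )
            cand_models = models.copy()
            for row in range(roi_idx.size):
                cand_models[row, :, e] = _model_phasors_q(
                    q_all[row], np.array([omega_new[row]]), dts[e : e + 1]
                )[:, 0]
            cand_offsets = offsets.copy()
            cand_offsets[:, e] = phi_new
            if _total_objective(vals_roi, cand_offsets, cand_models, dts) <= \
               _total_objective(vals_roi, offsets, models, dts):
                offsets[:, e] = phi_new
                omega[roi_idx, e] = omega_new
                models = cand_models

        total = _total_objective(vals_roi, offsets, models, dts)
        if np.isfinite(prev_total) and prev_total - total < tol:
            break
        prev_total = total

    result = MicroShiftResult(
        omega_A_hat=omega,
        residual=resid,
        intervals=intervals,
        echo_times_ms=scheme.fitted_echo_times_ms,
        offsets=offsets,
        ill_conditioned=flagged,
        meta={"total_objective": total, "interval_mode": interval_mode},
    )
    return offsets, result


def _pe_objective(
    y: np.ndarray, offset: float, models: np.ndarray, dt: float
) -> float:
    data = np.exp(1j * (y - offset) * dt)
    inner = np.real(np.conj(models) * data)
    d = np.arccos(np.clip(inner, -1.0, 1.0))
    return float(np.sum(d * d))


def _delta_e_rows(q_all: np.ndarray, a: np.ndarray) -> np.ndarray:
    """δE per voxel/position at per-voxel phases ``a``: (V, P)."""
    from .forward import _zonal_phase_coeffs

    lam = _zonal_phase_coeffs(a)  # (V, L)
    return np.einsum("vl,vpl->vp", lam, q_all)


def _refine_echo(
    y_e: np.ndarray,
    q_all: np.ndarray,
    dt: float,
    phi0: np.ndarray,
    omega0: np.ndarray,
    omega_bounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Gauss–Newton refinement of (φ, ω) at one echo.

    Minimizes the signed wrapped-phase residuals
    ``r_vp = arg( exp(i(y − φ_p)Δt) · conj(sgn δE_v(ω_v)) )`` — whose
    squares equal the phase-metric objective — over the per-position
    offsets and per-voxel shifts simultaneously.  The alternating updates
    move very slowly along the nearly degenerate direction that trades a
    common offset against compensating voxel shifts; the joint step
    converges there quadratically.
    """
    n_vox, n_pos = y_e.shape
    eps = 1e-4  # rad/s, central-difference step for d(arg δE)/dω

    def residuals(x: np.ndarray) -> np.ndarray:
        phi, omega = x[:n_pos], x[n_pos:]
        model = _sgn(_delta_e_rows(q_all, omega * dt))
        data = np.exp(1j * (y_e - phi[None, :]) * dt)
        return np.angle(data * np.conj(model)).ravel()

    def jacobian(x: np.ndarray) -> np.ndarray:
        phi, omega = x[:n_pos], x[n_pos:]
        dplus = np.angle(
            _sgn(_delta_e_rows(q_all, (omega + eps) * dt))
            * np.conj(_sgn(_delta_e_rows(q_all, (omega - eps) * dt)))
        ) / (2.0 * eps)
        J = np.zeros((n_vox * n_pos, n_pos + n_vox))
        rows = np.arange(n_vox * n_pos)
        pcol = np.tile(np.arange(n_pos), n_vox)
        J[rows, pcol] = -dt
        vcol = n_pos + np.repeat(np.arange(n_vox), n_pos)
        J[rows, vcol] = -dplus.ravel()
        return J

    lo = np.concatenate([np.full(n_pos, -np.inf), omega_bounds[:, 0]])
    hi = np.concatenate([np.full(n_pos, np.inf), omega_bounds[:, 1]])
    x0 = np.clip(np.concatenate([phi0, omega0]), lo, hi)
    sol = least_squares(
        residuals, x0, jac=jacobian, bounds=(lo, hi),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=60,
    )
    return sol.x[:n_pos], sol.x[n_pos:]
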
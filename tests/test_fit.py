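"""Phase-metric estimator: single-echo fits, wrap tracking, offsets."""

import numpy as np
import pytest

from msai import (
    PhantomConfig,
    build_phantom,
    default_scheme,
    estimate_offsets,
    fit_voxel,
    mixture_odf,
    phase_distance,
    simulate_measurements,
    track_echo_train,
    watson_odf,
)
from msai.fit import _objective_on, _fit_q
from msai.forward import ensemble_signal_sh, sh_projection_at

from conftest import X, Z

T, T0 = 0.0405, 0.0045


def model_frequency(odf, omega, b0s, dt):
    """Noise-free model-implied measurement y per field direction."""
    y = np.empty(len(b0s))
    for p, b in enumerate(b0s):
        q = sh_projection_at(odf, b)
        y[p] = np.angle(ensemble_signal_sh(q, np.array([omega * dt]))[0]) / dt
    return y


class TestPhaseDistance:
    def test_identical_phase_is_zero(self, rng):
        for _ in range(5):
            z = rng.normal() + 1j * rng.normal()
            if abs(z) > 1e-12:
                assert phase_distance(z, 3.0 * z) < 1e-12

    @pytest.mark.parametrize(
        "z1,z2,expected",
        [(1, -1, np.pi), (1, 1j, np.pi / 2), (1j, -1j, np.pi)],
    )
    def test_reference_angles(self, z1, z2, expected):
        assert phase_distance(z1, z2) == pytest.approx(expected)

    def test_symmetry(self, rng):
        z1, z2 = 1.0 + 0.5j, -0.3 + 2j
        assert phase_distance(z1, z2) == pytest.approx(phase_distance(z2, z1))

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            phase_distance(0.0, 1.0)


class TestFitVoxel:
    def test_recovery_near_delta_perpendicular(self, delta_perpendicular):
        omega_true = -25.0
        y = model_frequency(delta_perpendicular, omega_true, [Z], T - T0)
        est, resid = fit_voxel(
            y, delta_perpendicular, np.array([Z]), T, T0, (-80.0, 80.0)
        )
        assert abs(est - omega_true) <= 1e-6 * max(1.0, abs(omega_true))
        assert resid >= 0

    def test_recovery_orthogonal_crossing_three_positions(self, scheme3):
        odf = mixture_odf(
            [(0.5, watson_odf(Z, 18.0)), (0.5, watson_odf(X, 18.0))]
        )
        omega_true = -40.0
        b0s = scheme3.b0_directions
        y = model_frequency(odf, omega_true, b0s, T - T0)
        est, _ = fit_voxel(y, odf, b0s, T, T0, (-80.0, 80.0))
        assert abs(est - omega_true) / abs(omega_true) < 1e-3

    def test_parallel_fiber_single_b0_flagged(self, delta_parallel, scheme3):
        """No orientation weighting for any b0 → flat objective, flagged."""
        scheme1 = default_scheme(1)
        y = np.zeros((1, scheme1.n_fitted_echoes))
        res = track_echo_train(y, delta_parallel, scheme1)
        assert res.ill_conditioned[0]

    def test_global_search_beats_random_interval_points(self, rng):
        odf = watson_odf(X, 8.0)
        omega_true = 30.0
        y = model_frequency(odf, omega_true, [Z], T - T0) + 0.4
        interval = (-77.0, 77.0)
        est, best = fit_voxel(y, odf, np.array([Z]), T, T0, interval)
        q = sh_projection_at(odf, Z)[None, :]
        phasors = np.exp(1j * y * (T - T0))
        random_obj = _objective_on(
            rng.uniform(*interval, size=50), q, phasors, T - T0
        )
        assert best <= random_obj.min() + 1e-12

    def test_empty_interval_rejected(self, uniform):
        with pytest.raises(ValueError):
            fit_voxel(np.zeros(1), uniform, np.array([Z]), T, T0, (1.0, 1.0))

    def test_noise_free_consistency_across_phantom(self, small_phantom, scheme3):
        """All tissue classes recover |ω(t−t0)| ≤ 0.9π within 1e-3 relative."""
        b0s = scheme3.b0_directions
        rng = np.random.default_rng(5)
        for name, odf in small_phantom.class_odfs.items():
            for omega_true in rng.uniform(-0.9, 0.9, size=3) * np.pi / (T - T0):
                y = model_frequency(odf, omega_true, b0s, T - T0)
                est, _ = fit_voxel(
                    y, odf, b0s, T, T0,
                    (-np.pi / (T - T0), np.pi / (T - T0)),
                )
                assert abs(est - omega_true) <= 1e-3 * max(1.0, abs(omega_true))


class TestTrackEchoTrain:
    def test_constant_shift_recovered_at_every_echo(self, scheme3):
        odf = watson_odf(X, 12.0)
        omega_true = -12.0
        times = scheme3.fitted_echo_times_ms * 1e-3
        t0 = scheme3.reference_time_ms * 1e-3
        y = np.stack(
            [
                model_frequency(odf, omega_true, scheme3.b0_directions, t - t0)
                for t in times
            ],
            axis=1,
        )
        res = track_echo_train(y, odf, scheme3)
        assert np.abs(res.omega_A_hat[0] - omega_true).max() < 1e-6 * max(
            1.0, abs(omega_true)
        )
        # estimates lie inside their reported intervals
        assert np.all(res.omega_A_hat[0] >= res.intervals[0, :, 0])
        assert np.all(res.omega_A_hat[0] <= res.intervals[0, :, 1])

    def test_first_echo_interval_centred_at_zero(self, scheme3):
        odf = watson_odf(X, 12.0)
        y = np.zeros((3, scheme3.n_fitted_echoes))
        res = track_echo_train(y, odf, scheme3)
        t1 = scheme3.fitted_echo_times_ms[0] * 1e-3
        np.testing.assert_allclose(
            res.intervals[0, 0], [-np.pi / t1, np.pi / t1]
        )

    def test_wrap_tracking_beats_naive_fit(self, scheme3):
        """Tracking follows a drifting shift through a phase wrap; a fit with
        the interval centred at 0 lands on the wrapped alias instead."""
        cfg = PhantomConfig(wm_peak_shift_hz=-16.0, grid_shape=(6, 1, 1))
        ph = build_phantom(cfg, scheme3)
        data = simulate_measurements(ph, scheme3)
        v = int(np.flatnonzero(ph.tissue_labels == 1)[0])  # perpendicular
        odf = ph.odf_for_voxel(v)
        truth = ph.truth_curves["perpendicular"].omega_A
        t_last = scheme3.fitted_echo_times_ms[-1] * 1e-3
        t0 = scheme3.reference_time_ms * 1e-3
        assert abs(truth[-1]) * (t_last - t0) > np.pi  # wrapped scenario

        res = track_echo_train(data.values[v], odf, scheme3)
        assert np.abs(res.omega_A_hat[0] - truth).max() < 1e-3 * np.abs(truth).max()

        naive, _ = fit_voxel(
            data.values[v][:, -1], odf, scheme3.b0_directions, t_last, t0,
            (-np.pi / t_last, np.pi / t_last),
        )
        assert abs(naive - truth[-1]) > 1.0  # missed the truth...
        # ...by one wrap: the voxel-scale phase responds to ω with slope
        # ≈ π̄·(t−t0), so the aliased branch sits 2π/((t−t0)·π̄) away
        from msai import orientation_weighting

        w = orientation_weighting(odf, scheme3.b0_directions[0])
        alias_offset = 2 * np.pi / ((t_last - t0) * w)
        assert abs(naive - (truth[-1] + alias_offset)) < 1.0


class TestEstimateOffsets:
    def test_zero_offsets_are_a_fixed_point(self, scheme3):
        scheme2 = default_scheme(2)
        ph = build_phantom(PhantomConfig(grid_shape=(6, 2, 1)), scheme2)
        data = simulate_measurements(ph, scheme2)
        offsets, _ = estimate_offsets(data, ph.voxel_odfs, scheme2)
        assert np.abs(offsets).max() < 1e-4

    def test_injected_offsets_recovered(self):
        scheme2 = default_scheme(2)
        cfg = PhantomConfig(offset_amplitude=1.0, seed=13, grid_shape=(6, 5, 2))
        ph = build_phantom(cfg, scheme2)
        data = simulate_measurements(ph, scheme2)
        offsets, res = estimate_offsets(data, ph.voxel_odfs, scheme2)
        assert np.abs(offsets - ph.offsets_true).max() < 1e-3
        assert res.meta["total_objective"] >= 0

    def test_single_position_rejected(self):
        scheme1 = default_scheme(1)
        ph = build_phantom(PhantomConfig(grid_shape=(6, 1, 1)), scheme1)
        data = simulate_measurements(ph, scheme1)
        with pytest.raises(ValueError):
            estimate_offsets(data, ph.voxel_odfs, scheme1)

    def test_total_error_is_monotone(self):
        """The alternation never increases the total objective."""
        scheme2 = default_scheme(2)
        cfg = PhantomConfig(offset_amplitude=0.8, seed=2, grid_shape=(6, 2, 1))
        ph = build_phantom(cfg, scheme2)
        data = simulate_measurements(
            ph, scheme2, sigma_y=0.05, seed=4
        )  # noise keeps the optimum away from an exact zero
        totals = []
        for max_iter in (1, 2, 3, 5):
            _, res = estimate_offsets(
                data, ph.voxel_odfs, scheme2, max_iter=max_iter
            )
            totals.append(res.meta["total_objective"])
        assert all(b <= a + 1e-12 for a, b in zip(totals, totals[1:]))
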
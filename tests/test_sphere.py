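"""Sphere grid, real SH basis, and Funk–Hecke convolution machinery."""

import numpy as np
import pytest
from scipy.integrate import quad

from msai import (
    funk_hecke_convolve,
    make_antipodal_grid,
    real_sh_basis,
    uniform_odf,
    watson_odf,
    zonal_kernel_coefficients,
)
from msai.odf import ODF, N_COEFFS
from msai.sphere import n_sh_coeffs

from conftest import random_unit_vectors


class TestAntipodalGrid:
    @pytest.mark.parametrize("n_half", [4, 30, 250, 500])
    def test_invariants(self, n_half):
        grid = make_antipodal_grid(n_half)
        assert grid.n_directions == 2 * n_half
        norms = np.linalg.norm(grid.directions, axis=1)
        assert np.abs(norms - 1).max() < 1e-12
        # exact antipodal pairing with shared weights
        assert np.array_equal(grid.directions[:n_half], -grid.directions[n_half:])
        assert np.array_equal(grid.weights[:n_half], grid.weights[n_half:])
        assert grid.weights.min() > 0
        assert abs(grid.weights.sum() - 4 * np.pi) < 1e-10

    def test_reference_size_500(self):
        grid = make_antipodal_grid(250)
        assert grid.n_directions == 500

    def test_constant_integrates_to_sphere_area(self, dense_grid):
        total = dense_grid.integrate(np.ones(dense_grid.n_directions))
        assert abs(total - 4 * np.pi) < 1e-10

    def test_quadratic_moment(self, dense_grid, rng):
        # ∫ <a,u>² du = 4π/3 for any unit a (cross-checked by 1D quadrature)
        oracle = 2 * np.pi * quad(lambda c: c * c, -1, 1)[0]
        assert abs(oracle - 4 * np.pi / 3) < 1e-12
        for a in random_unit_vectors(rng, 5):
            val = dense_grid.integrate((dense_grid.directions @ a) ** 2)
            assert abs(val - 4 * np.pi / 3) < 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_antipodal_grid(3)

    def test_quadrature_exactness_for_order8_products(self, dense_grid):
        """Gram matrix of the order-8 basis is the identity within 1e-6."""
        basis = real_sh_basis(dense_grid.directions, 8)
        gram = (basis * dense_grid.weights[:, None]).T @ basis
        assert np.abs(gram - np.eye(N_COEFFS)).max() < 1e-6


class TestRealSHBasis:
    def test_column_count(self):
        assert n_sh_coeffs(8) == 45
        dirs = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        assert real_sh_basis(dirs, 8).shape == (2, 45)

    def test_order0_is_constant(self, rng):
        basis = real_sh_basis(random_unit_vectors(rng, 10), 8)
        assert np.abs(basis[:, 0] - 1 / (2 * np.sqrt(np.pi))).max() < 1e-14

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            real_sh_basis(np.array([[0.0, 0.0, 1.0]]), 7)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            real_sh_basis(np.array([[0.0, 0.0, 2.0]]), 8)


class TestZonalKernelCoefficients:
    def test_constant_kernel(self, rng):
        lam = zonal_kernel_coefficients(lambda c: np.ones_like(c), 8)
        assert abs(lam[0] - 4 * np.pi) < 1e-10
        assert np.abs(lam[1:]).max() < 1e-12
        # convolution with any unit-mass ODF gives 1
        odf = watson_odf(np.array([0.0, 0.0, 1.0]), 7.0)
        for b0 in random_unit_vectors(rng, 3):
            assert abs(funk_hecke_convolve(odf, lam, b0) - 1.0) < 1e-10

    def test_sin_squared_kernel(self):
        # 1 − c² = (2/3)(P₀ − P₂): only degrees 0 and 2 survive
        lam = zonal_kernel_coefficients(lambda c: 1 - c * c, 8)
        assert abs(lam[0] - 8 * np.pi / 3) < 1e-10
        assert abs(lam[1] + 8 * np.pi / 15) < 1e-10
        assert np.abs(lam[2:]).max() < 1e-12
        val = funk_hecke_convolve(uniform_odf(), lam, np.array([0.0, 0.0, 1.0]))
        assert abs(val - 2.0 / 3.0) < 1e-10

    @pytest.mark.parametrize("a", [-np.pi, -1.0, 0.3, np.pi])
    def test_reconstruction_of_oscillatory_kernel(self, a):
        """Legendre expansion at elevated degree reproduces exp(i·a(1−c²))."""
        max_order = 24
        lam = zonal_kernel_coefficients(
            lambda c: np.exp(1j * a * (1 - c * c)), max_order
        )
        c = np.linspace(-1, 1, 64)
        from scipy.special import eval_legendre

        recon = np.zeros_like(c, dtype=complex)
        for idx, l in enumerate(range(0, max_order + 1, 2)):
            recon += lam[idx] * (2 * l + 1) / (4 * np.pi) * eval_legendre(l, c)
        # the kernel is even in c, so the odd-degree terms are zero and the
        # even-degree partial sum is the full expansion
        direct = np.exp(1j * a * (1 - c * c))
        assert np.abs(recon - direct).max() < 1e-8

    def test_nonfinite_kernel_rejected(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError):
                zonal_kernel_coefficients(lambda c: 1.0 / (c - c), 8)


class TestFunkHeckeConvolve:
    def test_uniform_odf_gives_kernel_mean(self, rng):
        lam = zonal_kernel_coefficients(lambda c: c * c, 8)
        vals = [
            funk_hecke_convolve(uniform_odf(), lam, b0)
            for b0 in random_unit_vectors(rng, 6)
        ]
        # mean of c² over the sphere is 1/3; also independent of b0
        assert np.abs(np.array(vals) - 1.0 / 3.0).max() < 1e-12
        assert np.ptp(np.real(vals)) < 1e-12

    def test_order_mismatch_rejected(self):
        lam = zonal_kernel_coefficients(lambda c: np.ones_like(c), 4)
        with pytest.raises(ValueError):
            funk_hecke_convolve(uniform_odf(), lam, np.array([0.0, 0.0, 1.0]))

    def test_agreement_with_direct_quadrature(self, dense_grid, rng):
        """SH and quadrature routes agree within 1e-6 on random triples."""
        from msai.odf import ODF

        basis = real_sh_basis(dense_grid.directions, 8)
        for _ in range(20):
            # random valid order-8 ODF: positive mixture of random Watsons
            mus = random_unit_vectors(rng, 2)
            w = rng.uniform(0.2, 0.8)
            c = (
                w * watson_odf(mus[0], rng.uniform(0, 15)).sh_coeffs
                + (1 - w) * watson_odf(mus[1], rng.uniform(0, 15)).sh_coeffs
            )
            odf = ODF(c)
            a = rng.uniform(-np.pi, np.pi)
            kernel = lambda x: np.exp(1j * a * (1 - x * x))
            lam = zonal_kernel_coefficients(kernel, 8)
            b0 = random_unit_vectors(rng, 1)[0]
            sh_val = funk_hecke_convolve(odf, lam, b0)
            integrand = kernel(dense_grid.directions @ b0) * (basis @ c)
            quad_val = dense_grid.integrate(integrand)
            assert abs(sh_val - quad_val) < 1e-6
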
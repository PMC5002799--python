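"""Analytic and oracle tests for the level-set building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselseg._grid import ETA2
from vesselseg.levelset import (
    LevelSetError,
    LevelSetParams,
    compute_edge_map,
    curvature_divergence,
    dirac,
    dynamic_threshold,
    edge_function,
    energy,
    initialize_levelset,
    penalty_energy,
    penalty_update,
    smooth_heaviside,
)


class TestHeavisideDirac:
    def test_closed_form_values(self):
        assert smooth_heaviside(0.0, 1.0) == pytest.approx(0.5)
        assert smooth_heaviside(1.0, 1.0) == pytest.approx(0.75)
        assert smooth_heaviside(-1.0, 1.0) == pytest.approx(0.25)
        assert dirac(0.0, 1.0) == pytest.approx(1.0 / np.pi)

    @given(phi=st.floats(-1e6, 1e6), eps=st.floats(0.01, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_complement_identity(self, phi, eps):
        assert smooth_heaviside(phi, eps) + smooth_heaviside(-phi, eps) == pytest.approx(1.0, abs=1e-12)

    @given(phi=st.floats(-50.0, 50.0), eps=st.floats(0.5, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_dirac_is_derivative_of_heaviside(self, phi, eps):
        h = 1e-4
        fd = (smooth_heaviside(phi + h, eps) - smooth_heaviside(phi - h, eps)) / (2 * h)
        assert dirac(phi, eps) == pytest.approx(fd, abs=1e-6)

    def test_dirac_integrates_to_one(self):
        x = np.linspace(-1e4, 1e4, 2_000_001)
        assert np.trapezoid(dirac(x, 1.0), x) == pytest.approx(1.0, abs=1e-3)

    def test_monotonicity_and_parameter_errors(self):
        x = np.linspace(-5, 5, 101)
        assert np.all(np.diff(smooth_heaviside(x, 2.0)) > 0)
        with pytest.raises(ValueError):
            smooth_heaviside(x, 0.0)
        with pytest.raises(ValueError):
            dirac(x, -1.0)


class TestEdgeMap:
    def test_edge_function_values(self):
        np.testing.assert_allclose(edge_function([0.0, 1.0, 3.0]), [1.0, 0.5, 0.1])

    def test_constant_volume_gives_unit_edge_map(self):
        g = compute_edge_map(np.full((8, 8, 8), 42.0), sigma_edge=1.0)
        np.testing.assert_allclose(g, 1.0, atol=1e-12)

    def test_linear_ramp_interior_value(self):
        # data = axis-0 index, no smoothing: central-difference gradient 1
        vol = np.broadcast_to(np.arange(5.0)[:, None, None], (5, 5, 5)).copy()
        g = compute_edge_map(vol, sigma_edge=0.0)
        np.testing.assert_allclose(g[1:-1], 0.5, atol=1e-12)

    def test_step_volume_minimum_on_step_face(self):
        vol = np.zeros((8, 8, 8))
        vol[4:] = 200.0
        g = compute_edge_map(vol, sigma_edge=1.0)
        imin = np.unravel_index(np.argmin(g), g.shape)
        assert imin[0] in (3, 4)


class TestDynamicThreshold:
    def test_constant_inside_returns_scaled_intensity(self):
        vol = np.full((12, 12, 12), 130.0)
        phi = np.full_like(vol, 10.0)
        mu1 = dynamic_threshold(vol, phi, k=1.0, sigma_local=2.0, epsilon=1.0)
        np.testing.assert_allclose(mu1, 130.0, atol=1e-6)
        mu_half = dynamic_threshold(vol, phi, k=0.5, sigma_local=2.0, epsilon=1.0)
        np.testing.assert_allclose(mu_half, 65.0, atol=1e-6)

    def test_matches_brute_force_convolution(self, smooth_random_volume, rng):
        """Oracle: explicit dense 3D kernel sum with replicate padding."""
        vol = smooth_random_volume
        phi = rng.normal(0.0, 3.0, size=vol.shape)
        sigma, eps, k = 2.0, 1.0, 0.8
        mu = dynamic_threshold(vol, phi, k=k, sigma_local=sigma, epsilon=eps)

        radius = int(np.ceil(3.0 * sigma))
        x = np.arange(-radius, radius + 1, dtype=float)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        h = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))
        num_f = np.pad(h * vol, radius, mode="edge")
        den_f = np.pad(h, radius, mode="edge")
        expected = np.empty_like(vol)
        n = vol.shape[0]
        for i in range(n):
            for j in range(n):
                for l in range(n):
                    w = np.s_[i:i + 2 * radius + 1, j:j + 2 * radius + 1,
                              l:l + 2 * radius + 1]
                    expected[i, j, l] = (k * np.sum(kernel * num_f[w])
                                         / np.sum(kernel * den_f[w]))
        np.testing.assert_allclose(mu, expected, atol=1e-6)

    def test_fallback_where_contour_weight_vanishes(self):
        vol = np.full((10, 10, 10), 300.0)
        phi = np.full_like(vol, -1e8)  # H(phi) ~ 0 everywhere
        with pytest.warns(RuntimeWarning):
            mu = dynamic_threshold(vol, phi, k=0.9, sigma_local=2.0, epsilon=1.0,
                                   fallback=200.0)
        np.testing.assert_allclose(mu, 200.0)

    def test_k_out_of_range_rejected(self):
        vol = np.zeros((4, 4, 4))
        with pytest.raises(ValueError):
            dynamic_threshold(vol, vol, k=0.3, sigma_local=2.0, epsilon=1.0)


class TestCurvature:
    def test_planar_field_has_zero_curvature(self):
        x = np.arange(16.0)
        phi = np.broadcast_to(x[:, None, None], (16, 16, 16)).copy()
        kappa = curvature_divergence(phi)
        np.testing.assert_allclose(kappa[2:-2, 2:-2, 2:-2], 0.0, atol=1e-12)

    def test_sphere_curvature_is_two_over_radius(self):
        n, R = 32, 8.0
        c = (n - 1) / 2.0
        i, j, k = np.indices((n, n, n)).astype(float)
        r = np.sqrt((i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2)
        phi = r - R  # positive outside; curvature of div(grad phi/|grad phi|) = 2/r
        kappa = curvature_divergence(phi)
        near = np.abs(r - R) < 1.0
        assert np.mean(kappa[near]) == pytest.approx(2.0 / R, rel=0.10)

    def test_matches_independent_stencil_composition(self, rng):
        """Oracle: the same replicate-boundary central differences composed
        voxel by voxel in plain Python loops."""
        phi = rng.normal(0.0, 1.0, size=(8, 8, 8))

        def cd(f, axis):
            out = np.empty_like(f)
            n = f.shape[axis]
            for idx in range(n):
                hi = f.take(min(idx + 1, n - 1), axis=axis)
                lo = f.take(max(idx - 1, 0), axis=axis)
                sl = [slice(None)] * 3
                sl[axis] = idx
                out[tuple(sl)] = 0.5 * (hi - lo)
            return out

        gx, gy, gz = cd(phi, 0), cd(phi, 1), cd(phi, 2)
        norm = np.sqrt(gx**2 + gy**2 + gz**2 + ETA2)
        expected = cd(gx / norm, 0) + cd(gy / norm, 1) + cd(gz / norm, 2)
        np.testing.assert_allclose(curvature_divergence(phi), expected, atol=1e-10)


class TestPenalty:
    def test_zero_on_exact_unit_slope_plane(self):
        x, y = np.arange(16.0), np.arange(16.0)
        phi = (0.6 * x[:, None, None] + 0.8 * y[None, :, None]
               + np.zeros((16, 16, 16)))
        assert np.abs(penalty_update(phi)).max() < 0.05

    def test_quadratic_half_space_value(self):
        # phi = x^2 / 2 for x > 0: lap = 1, curvature term 0, update = 1
        x = np.arange(1.0, 25.0)
        phi = np.broadcast_to(0.5 * x[:, None, None] ** 2, (24, 12, 12)).copy()
        upd = penalty_update(phi)
        np.testing.assert_allclose(upd[2:-2, 2:-2, 2:-2], 1.0, atol=1e-9)

    def test_explicit_iteration_restores_unit_gradient_monotonically(self):
        x = np.arange(32.0)
        phi = 2.0 * np.broadcast_to(x[:, None, None], (32, 32, 32)).copy()

        def mean_dev(f):
            g = np.array(np.gradient(f))
            return float(np.mean(np.abs(np.sqrt((g**2).sum(axis=0)) - 1.0)))

        devs = [mean_dev(phi)]
        for _ in range(50):
            phi = phi + 0.2 * penalty_update(phi)
            devs.append(mean_dev(phi))
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(devs, devs[1:]))
        assert devs[-1] < devs[0]

    def test_penalty_energy_zero_for_sdf_and_linear_in_gamma(self):
        x, y = np.arange(16.0), np.arange(16.0)
        sdf = (0.6 * x[:, None, None] + 0.8 * y[None, :, None]
               + np.zeros((16, 16, 16)))
        assert penalty_energy(sdf) < 1e-6 * sdf.size


class TestEnergy:
    def _params(self, **kw):
        defaults = dict(alpha1=0.003, alpha2=0.0, beta=0.0, gamma=0.0,
                        epsilon=0.01)
        defaults.update(kw)
        return LevelSetParams(**defaults)

    def test_empty_contour_energy_near_zero(self):
        n = 12
        x = np.arange(float(n))
        phi = -(x[:, None, None] + 5.0) + np.zeros((n, n, n))  # exact SDF, all < 0
        vol = np.full((n, n, n), 1.0)
        p = LevelSetParams(alpha1=0.003, alpha2=0.003, beta=0.02, gamma=1.0,
                           epsilon=0.01)
        e = energy(vol, phi, np.full_like(vol, 0.5), np.ones_like(vol), p)
        assert abs(e) < 1e-3 * phi.size

    def test_binary_half_volume_hand_sum(self):
        # alpha2 = beta = gamma = 0, I in {0, 300}, mu0 = 200, eps = 0.01:
        # E ~ -alpha1 * (300 - 200) * 32 = -9.6 on a 4^3 grid half bright
        vol = np.zeros((4, 4, 4))
        vol[:2] = 300.0
        phi = np.where(vol > 0, 1.0, -1.0)
        p = self._params(mu0=200.0)
        e = energy(vol, phi, np.zeros_like(vol), np.ones_like(vol), p)
        assert e == pytest.approx(-9.6, rel=0.02)

    def test_penalty_contribution_linear_in_gamma(self, rng):
        phi = rng.normal(0.0, 2.0, size=(10, 10, 10))
        vol = np.zeros_like(phi)
        mu = np.zeros_like(phi)
        g = np.ones_like(phi)
        e1 = energy(vol, phi, mu, g, self._params(alpha1=0.0, gamma=1.0))
        e2 = energy(vol, phi, mu, g, self._params(alpha1=0.0, gamma=2.0))
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            energy(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)), 0.0,
                   np.ones((4, 4, 4)), self._params())


class TestInitialization:
    def test_ball_indicator_gives_signed_distance(self):
        n, c = 24, 12.0
        i, j, k = np.indices((n, n, n)).astype(float)
        r = np.sqrt((i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2)
        vness = (r <= 4.0).astype(float)
        phi = initialize_levelset(np.zeros((n, n, n)), vness, v_threshold=0.5,
                                  band_value=6.0)
        assert abs(phi[12, 12, 12] - 4.0) < 0.6
        assert phi[0, 0, 0] < 0
        # zero level set within one voxel of the region boundary (brute force)
        surface = np.abs(r - 4.0) < 0.5
        assert np.all(np.abs(phi[surface]) <= 1.0)

    def test_empty_and_full_regions_rejected(self):
        vol = np.zeros((8, 8, 8))
        with pytest.raises(LevelSetError):
            initialize_levelset(vol, np.zeros_like(vol), 0.5, 6.0)
        with pytest.raises(LevelSetError):
            initialize_levelset(vol, np.ones_like(vol), 0.5, 6.0)

    def test_band_clamp_and_sign_structure(self):
        n = 24
        vness = np.zeros((n, n, n))
        vness[8:16, 8:16, :] = 1.0
        phi = initialize_levelset(np.zeros((n, n, n)), vness, 0.5, band_value=3.0)
        assert phi.max() <= 3.0 and phi.min() >= -3.0
        assert (phi > 0).any() and (phi < 0).any()
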
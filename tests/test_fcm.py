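"""Grid FCM solver: spreading moments, Stokes solve, drag oracles."""

import numpy as np
import pytest

from spermflow.params import GridSpec
from spermflow.mobility.fcm import (FluidField, fcm_interpolate, fcm_mobility,
                                    fcm_spread, sigma_monopole,
                                    stokes_solve_periodic)
from spermflow.mobility.shapes import (ellipsoid_rotation_radius,
                                       ellipsoid_translation_radius)


@pytest.fixture(scope="module")
def cube():
    return GridSpec(L=40.0, L_z=40.0, N_x=128, N_y=128, N_z=128)


class TestSpread:
    def test_force_monopole_integral(self, cube):
        f = fcm_spread([[20.0, 20.0, 20.0]], [1.0],
                       F=np.array([[1.0, 0.0, 0.0]]), grid=cube)
        total = f.f_grid.sum(axis=(1, 2, 3)) * cube.dx ** 3
        assert np.allclose(total, [1.0, 0.0, 0.0], atol=1e-10)

    def test_torque_dipole_moments(self, cube):
        T = np.array([[0.3, -1.2, 0.7]])
        f = fcm_spread([[20.0, 20.0, 20.0]], [1.0], T=T, grid=cube)
        dV = cube.dx ** 3
        assert np.allclose(f.f_grid.sum(axis=(1, 2, 3)) * dV, 0.0, atol=1e-10)
        x = (np.arange(cube.N_x) * cube.dx - 20.0)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        fx, fy, fz = f.f_grid
        moment = np.array([
            np.sum(Y * fz - Z * fy), np.sum(Z * fx - X * fz),
            np.sum(X * fy - Y * fx)]) * dV
        assert np.allclose(moment, T[0], atol=1e-8)

    def test_opposite_forces_cancel_at_zero_mode(self, cube):
        F = np.array([[1.0, 0.5, -0.2], [-1.0, -0.5, 0.2]])
        f = fcm_spread([[15.0, 20.0, 20.0], [25.0, 20.0, 20.0]],
                       [1.0, 1.0], F=F, grid=cube)
        assert np.allclose(f.f_grid.sum(axis=(1, 2, 3)), 0.0, atol=1e-12)

    def test_unresolved_envelope_rejected(self):
        g = GridSpec(L=40.0, L_z=40.0, N_x=32, N_y=32, N_z=32)
        with pytest.raises(ValueError, match="unresolved"):
            fcm_spread([[20.0, 20.0, 20.0]], [1.0],
                       F=np.array([[1.0, 0, 0]]), grid=g)


class TestStokesSolve:
    def test_single_mode_closed_form(self, cube):
        """f = A sin(k0 x) y_hat gives u = A/(eta k0^2) sin(k0 x) y_hat."""
        k0 = 2 * np.pi * 3 / cube.L
        x = np.arange(cube.N_x) * cube.dx
        f = np.zeros((3,) + cube.shape)
        f[1] = 2.5 * np.sin(k0 * x)[:, None, None]
        eta = 1.7
        u = stokes_solve_periodic(FluidField(grid=cube, f_grid=f), eta=eta).u
        expect = 2.5 / (eta * k0 ** 2) * np.sin(k0 * x)
        assert np.allclose(u[1], expect[:, None, None], atol=1e-12)
        assert np.allclose(u[0], 0.0, atol=1e-12)

    def test_divergence_free(self, cube, rng):
        f = rng.normal(size=(3, 32, 32, 32))
        f -= f.mean(axis=(1, 2, 3), keepdims=True)
        g = GridSpec(L=40.0, L_z=40.0, N_x=32, N_y=32, N_z=32)
        field = stokes_solve_periodic(FluidField(grid=g, f_grid=f))
        assert field.divergence_norm() < 1e-12

    def test_nonzero_mean_rejected_in_strict_mode(self, cube):
        f = np.ones((3, 16, 16, 16))
        g = GridSpec(L=16.0, L_z=16.0, N_x=16, N_y=16, N_z=16)
        with pytest.raises(ValueError, match="mean"):
            stokes_solve_periodic(FluidField(grid=g, f_grid=f),
                                  remove_mean=False)

    def test_far_field_matches_oseen(self):
        """Regularized point force -> Oseen tensor at sigma << r << L/4.

        The periodic images add a nearly uniform backflow at these radii,
        so the free-space 1/(4 pi eta r) law is checked on the difference
        of the flow between two radii along the force axis.
        """
        g = GridSpec(L=60.0, L_z=60.0, N_x=160, N_y=160, N_z=160)
        c = 30.0
        field = fcm_spread([[c, c, c]], [1.0], F=np.array([[1.0, 0, 0]]),
                           grid=g)
        u = stokes_solve_periodic(field).u
        j = k = int(c / g.dx)
        rs = np.array([4.5, 6.0, 7.5, 9.0, 10.5, 12.0])
        vals = np.array([u[0][int((c + r) / g.dx), j, k] for r in rs])
        # fit A/r + B: the constant absorbs the uniform image backflow;
        # the remaining bias is the O(r^2/L^3) image-lattice gradient
        design = np.vstack([1 / rs, np.ones_like(rs)]).T
        A = np.linalg.lstsq(design, vals, rcond=None)[0][0]
        assert A == pytest.approx(1.0 / (4 * np.pi), rel=0.05)


class TestInterpolate:
    def test_uniform_field(self, cube):
        field = FluidField(grid=cube,
                           u=np.ones((3,) + cube.shape) * [[[[2.0]]], [[[0.5]]],
                                                           [[[-1.0]]]])
        U, W = fcm_interpolate(field, [[13.3, 21.7, 8.2]], [1.0])
        assert np.allclose(U[0], [2.0, 0.5, -1.0], atol=1e-10)
        assert np.allclose(W[0], 0.0, atol=1e-12)

    def test_rigid_rotation_field(self):
        """u = omega x r (windowed) recovers W ~ omega."""
        g = GridSpec(L=40.0, L_z=40.0, N_x=128, N_y=128, N_z=128)
        omega = np.array([0.0, 0.0, 0.4])
        x = np.arange(g.N_x) * g.dx - 20.0
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r2 = X ** 2 + Y ** 2 + Z ** 2
        win = np.exp(-r2 / (2 * 6.0 ** 2))
        u = np.stack([-omega[2] * Y * win, omega[2] * X * win,
                      np.zeros_like(X)])
        U, W = fcm_interpolate(FluidField(grid=g, u=u),
                               [[20.0, 20.0, 20.0]], [1.0])
        assert W[0, 2] == pytest.approx(0.4, rel=0.02)
        assert np.allclose(U[0], 0.0, atol=1e-10)


class TestMobility:
    def test_hasimoto_drag(self, cube):
        """Isolated periodic drag matches the Hasimoto-corrected Stokes law."""
        U, _ = fcm_mobility([[20.0, 20.0, 20.0]], [1.0],
                            F=np.array([[1.0, 0, 0]]), grid=cube)
        expect = 1.0 / (6 * np.pi) * (1 - 2.8373 / cube.L)
        assert U[0, 0] == pytest.approx(expect, rel=0.01)
        assert abs(U[0, 1]) < 1e-8 and abs(U[0, 2]) < 1e-8

    def test_rotational_drag(self, cube):
        _, W = fcm_mobility([[20.0, 20.0, 20.0]], [1.0],
                            T=np.array([[0, 0, 1.0]]), grid=cube)
        assert W[0, 2] == pytest.approx(1.0 / (8 * np.pi), rel=0.02)

    def test_zero_input_zero_output(self, cube):
        U, W = fcm_mobility([[20.0, 20.0, 20.0]], [1.0],
                            F=np.zeros((1, 3)), T=np.zeros((1, 3)), grid=cube)
        assert not U.any() and not W.any()

    def test_linearity(self, rng):
        g = GridSpec(L=20.0, L_z=20.0, N_x=64, N_y=64, N_z=64)
        pos = rng.uniform(4, 16, size=(3, 3))
        F1, F2 = rng.normal(size=(2, 3, 3))
        Ua, _ = fcm_mobility(pos, np.ones(3), F=F1, grid=g,
                             want_angular=False)
        Ub, _ = fcm_mobility(pos, np.ones(3), F=F2, grid=g,
                             want_angular=False)
        Uc, _ = fcm_mobility(pos, np.ones(3), F=2.0 * F1 - 0.5 * F2, grid=g,
                             want_angular=False)
        assert np.allclose(Uc, 2.0 * Ua - 0.5 * Ub, atol=1e-10)

    def test_reciprocity_and_dissipativity(self, rng):
        g = GridSpec(L=20.0, L_z=20.0, N_x=64, N_y=64, N_z=64)
        pos = rng.uniform(4, 16, size=(4, 3))
        F1, F2 = rng.normal(size=(2, 4, 3))
        T1, T2 = rng.normal(size=(2, 4, 3))
        U1, W1 = fcm_mobility(pos, np.ones(4), F=F1, T=T1, grid=g)
        U2, W2 = fcm_mobility(pos, np.ones(4), F=F2, T=T2, grid=g)
        p12 = np.sum(U1 * F2) + np.sum(W1 * T2)
        p21 = np.sum(U2 * F1) + np.sum(W2 * T1)
        assert p12 == pytest.approx(p21, abs=1e-10 * max(abs(p12), 1e-30))
        assert np.sum(U1 * F1) + np.sum(W1 * T1) >= 0.0
        assert np.sum(U2 * F2) + np.sum(W2 * T2) >= 0.0


class TestEffectiveRadii:
    def test_sphere_limits(self):
        assert ellipsoid_translation_radius((2.0, 2.0, 2.0), 0) == \
            pytest.approx(2.0, rel=1e-8)
        assert ellipsoid_rotation_radius((2.0, 2.0, 2.0), 2) == \
            pytest.approx(2.0, rel=1e-8)

    def test_oblate_head_between_axes(self):
        a_t = ellipsoid_translation_radius((3.0, 3.0, 1.0), 0)
        a_r = ellipsoid_rotation_radius((3.0, 3.0, 1.0), 2)
        assert 1.0 < a_t < 3.0
        assert 1.0 < a_r < 3.0
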
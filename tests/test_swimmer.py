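"""Swimmer model: actuation, elasticity and constraint mechanics."""

import numpy as np
import pytest

from spermflow import swimmer as sw
from spermflow.params import PhysicalParams


def bent_swimmer(params, rng, n_flag=12, amplitude=0.3):
    """An admissible swimmer with randomly curved flagellum."""
    state = sw.straight_swimmer(params, n_flag)
    th = np.cumsum(np.concatenate(
        [[0.0, 0.0], rng.uniform(-amplitude, amplitude, n_flag - 1)]))
    return rebuild(state, th, params)


def rebuild(state, theta, params):
    """Chain positions from angles so every joint constraint is satisfied."""
    n_flag = state.n_flag
    ds = params.l / n_flag
    pos = np.zeros_like(state.pos)
    t = np.stack([np.cos(theta), np.sin(theta),
                  np.zeros_like(theta)], axis=-1)
    pos[0] = state.pos[0]
    pos[1] = pos[0] + params.head_offset * t[0] + 0.5 * ds * t[1]
    for j in range(2, n_flag + 1):
        pos[j] = pos[j - 1] + 0.5 * ds * (t[j - 1] + t[j])
    out = state.copy()
    out.pos, out.theta = pos, np.asarray(theta, dtype=float)
    return out


class TestPreferredCurvature:
    def test_zero_at_base_for_zero_phase(self, params):
        assert sw.preferred_curvature(0.0, 0.0, 0.0, params) == 0.0

    def test_zero_at_tip_any_phase(self, params):
        for ph in (0.0, 1.0, 2.5):
            assert sw.preferred_curvature(params.l, ph, 0.3, params) == \
                pytest.approx(0.0, abs=1e-15)

    def test_bounded_by_amplitude(self, params):
        s = np.linspace(0, params.l, 400)
        for Phi in np.linspace(0, 2 * np.pi, 7):
            kap = sw.preferred_curvature(s, 0.0, Phi, params)
            assert np.all(np.abs(kap) <= params.K0 + 1e-15)
        assert params.K0 * params.l == pytest.approx(12.76)

    def test_outside_domain_rejected(self, params):
        with pytest.raises(ValueError):
            sw.preferred_curvature(-1.0, 0, 0, params)
        with pytest.raises(ValueError):
            sw.preferred_curvature(params.l + 1.0, 0, 0, params)

    def test_ramp_is_linear_near_tip(self, params):
        l, g = params.l, params.gamma_tip
        mid = l * (1 - 0.5 * g)
        assert sw.ramp_amplitude(mid, params) == pytest.approx(0.5)
        assert sw.ramp_amplitude(l * (1 - g), params) == pytest.approx(1.0)


class TestBendingTorques:
    def test_straight_filament_has_no_torque(self, params):
        state = sw.straight_swimmer(params, 10)
        assert np.allclose(sw.bending_torques(state, params), 0.0)

    def test_circular_arc_matches_continuum(self, params, rng):
        """Discrete arc torque = K_B kappa + O((kappa ds)^2)."""
        n_flag = 20
        ds = params.l / n_flag
        kappa = 0.02  # kappa * ds = 0.044 << 1
        state = sw.straight_swimmer(params, n_flag)
        th = np.concatenate([[0.0], kappa * ds * np.arange(n_flag)])
        state = rebuild(state, th, params)
        T = sw.bending_torques(state, params)
        # interior joint torque on segment j (pair +/-): net per segment is
        # zero in the bulk; compare the tip segment's torque magnitude
        tip = abs(T[-1, 2])
        assert tip == pytest.approx(params.K_B * kappa,
                                    rel=(kappa * ds) ** 2 * 5 + 1e-9)

    def test_torques_are_energy_gradient(self, params, rng):
        """Bending+driving torques = -dE/dtheta (finite differences)."""
        state = bent_swimmer(params, rng)
        state.Phi = 0.7
        T = sw.driving_torques(state, params)
        eps = 1e-6
        for j in range(1, state.n_flag + 1):
            th = state.theta.copy()
            th[j] += eps
            ep = sw.driven_elastic_energy(rebuild(state, th, params), params)
            th[j] -= 2 * eps
            em = sw.driven_elastic_energy(rebuild(state, th, params), params)
            grad = (ep - em) / (2 * eps)
            # rebuild() moves downstream positions too, but the energy
            # depends only on angles, so the gradient is the pure torque
            assert -grad == pytest.approx(T[j, 2], rel=1e-4, abs=1e-6)

    def test_preferred_configuration_is_equilibrium(self, params):
        """A flagellum bent exactly to kappa_0 feels no elastic torque."""
        n_flag = 29
        ds = params.l / n_flag
        state = sw.straight_swimmer(params, n_flag)
        state.Phi = 1.1
        kap0 = sw.preferred_curvature(
            sw.joint_arclengths(n_flag, params), state.phi, state.Phi, params)
        # choose joint angles with sin(dtheta)/ds = kappa_0
        dth = np.arcsin(kap0 * ds)
        th = np.concatenate([[0.0, 0.0], np.cumsum(dth)])
        state = rebuild(state, th, params)
        T = sw.driving_torques(state, params)
        assert np.max(np.abs(T)) < 1e-10 * params.K_B * params.K0

    def test_actuation_is_internal(self, params, rng):
        state = bent_swimmer(params, rng)
        assert np.allclose(sw.driving_torques(state, params).sum(axis=0),
                           0.0, atol=1e-12 * params.K_B)


class TestConstraints:
    def test_straight_swimmer_admissible(self, params):
        state = sw.straight_swimmer(params, 29)
        g, clamp = sw.constraint_residuals(state, params)
        assert np.max(np.abs(g)) < 1e-12
        assert np.max(np.abs(clamp)) < 1e-12

    def test_stretched_joint_residual(self, params):
        state = sw.straight_swimmer(params, 10)
        delta = 0.37
        t = state.t_hat[5]
        state.pos[5:] += delta * t
        g, _ = sw.constraint_residuals(state, params)
        assert np.linalg.norm(g[4]) == pytest.approx(delta, rel=1e-12)

    def test_residuals_match_bruteforce(self, params, rng):
        """Residuals equal a direct evaluation of the defining formulas."""
        state = bent_swimmer(params, rng)
        state.pos += rng.normal(scale=0.1, size=state.pos.shape)
        g, clamp = sw.constraint_residuals(state, params)
        ds = params.l / state.n_flag
        t = state.t_hat
        for j in range(1, state.n_flag):
            expect = state.pos[j + 1] - state.pos[j] \
                - 0.5 * ds * (t[j] + t[j + 1])
            assert np.allclose(g[j], expect)
        expect0 = state.pos[1] - 0.5 * ds * t[1] - state.pos[0] \
            - 1.1 * params.a * t[0]
        assert np.allclose(g[0], expect0)
        assert np.allclose(clamp, t[1] - t[0])

    def test_zero_multipliers_zero_forces(self, params):
        state = sw.straight_swimmer(params, 8)
        F, T = sw.constraint_forces(state, np.zeros((8, 3)), 0.0, params)
        assert not F.any() and not T.any()

    def test_single_multiplier_localized(self, params):
        state = sw.straight_swimmer(params, 8)
        Lam = np.zeros((8, 3))
        Lam[4] = [1.0, -2.0, 0.0]
        F, _ = sw.constraint_forces(state, Lam, 0.0, params)
        assert np.allclose(F[4], Lam[4])      # segment before the joint
        assert np.allclose(F[5], -Lam[4])     # segment after
        mask = np.ones(9, bool)
        mask[[4, 5]] = False
        assert not F[mask].any()
        assert np.allclose(F.sum(axis=0), 0.0)

    def test_virtual_work_oracle(self, params, rng):
        """F_C = -d(Lambda . g)/d(positions) by finite differences."""
        state = bent_swimmer(params, rng)
        Lam = rng.normal(size=(state.n_flag, 3))
        Lam[:, 2] = 0.0
        F, _ = sw.constraint_forces(state, Lam, 0.0, params)
        eps = 1e-7

        def work(pos):
            s2 = state.copy()
            s2.pos = pos
            g, _ = sw.constraint_residuals(s2, params)
            return np.sum(Lam * g)

        for b in [0, 1, 4, state.n_flag]:
            for c in range(2):
                pos = state.pos.copy()
                pos[b, c] += eps
                wp = work(pos)
                pos[b, c] -= 2 * eps
                wm = work(pos)
                assert -(wp - wm) / (2 * eps) == pytest.approx(
                    F[b, c], rel=1e-6, abs=1e-6)

    def test_mismatched_multiplier_count(self, params):
        state = sw.straight_swimmer(params, 8)
        with pytest.raises(ValueError):
            sw.constraint_forces(state, np.zeros((5, 3)), 0.0, params)


class TestForceBalance:
    def test_zero_net_force_and_torque(self, params, rng):
        """Internal forces exert no net force/torque on an admissible swimmer."""
        state = bent_swimmer(params, rng, n_flag=29)
        state.Phi = 0.4
        Lam = rng.normal(scale=50.0, size=(29, 3))
        Lam[:, 2] = 0.0
        bundle = sw.assemble_swimmer_forces(state, Lam, rng.normal(), params)
        F = bundle.total_force
        T = bundle.total_torque
        com = state.pos.mean(axis=0)
        net_F = F.sum(axis=0)
        net_T = T.sum(axis=0) + np.cross(state.pos - com, F).sum(axis=0)
        scale = np.abs(F).max() * params.l
        assert np.linalg.norm(net_F) < 1e-10 * max(np.abs(F).max(), 1.0)
        assert np.linalg.norm(net_T) < 1e-10 * max(scale, 1.0)


class TestPlanarVectorizedPath:
    def test_matches_single_swimmer_api(self, params, rng):
        """The vectorized planar assembly equals the 3-vector reference."""
        states = [bent_swimmer(params, rng, n_flag=15) for _ in range(3)]
        for st, ph in zip(states, (0.0, 1.0, 2.0)):
            st.Phi = ph
        x = np.stack([s.pos[:, :2] for s in states])
        th = np.stack([s.theta for s in states])
        Lam3 = rng.normal(scale=10.0, size=(3, 15, 3))
        Lam3[..., 2] = 0.0
        mu = rng.normal(size=3)
        phase = np.array([s.Phi + s.phi for s in states])
        F, Tz, g, h = sw.planar_internal_forces(
            x, th, Lam3[..., :2], mu, phase, params)
        for i, st in enumerate(states):
            bundle = sw.assemble_swimmer_forces(
                st, Lam3[i], mu[i], params)
            assert np.allclose(F[i], bundle.total_force[:, :2], atol=1e-10)
            assert np.allclose(Tz[i], bundle.total_torque[:, 2], atol=1e-10)
            gg, cl = sw.constraint_residuals(st, params)
            assert np.allclose(g[i], gg[:, :2], atol=1e-12)


class TestCurvatureProperties:
    from hypothesis import given, settings as _hs, strategies as _st

    @given(frac=_st.floats(0.0, 1.0), phi=_st.floats(0.0, 6.283),
           Phi=_st.floats(-100.0, 100.0))
    @_hs(deadline=None, max_examples=60, derandomize=True)
    def test_bounded_and_tip_ramped(self, frac, phi, Phi):
        """|kappa_0| <= K0 everywhere; vanishes at the free end."""
        params = PhysicalParams.reference()
        s = frac * params.l
        k = sw.preferred_curvature(s, phi, Phi, params)
        assert abs(k) <= params.K0 * (1.0 + 1e-12)
        assert sw.preferred_curvature(params.l, phi, Phi, params) == \
            pytest.approx(0.0, abs=1e-15)

    @given(seed=_st.integers(0, 2 ** 16))
    @_hs(deadline=None, max_examples=25, derandomize=True)
    def test_constraint_forces_always_balance(self, seed):
        """Net constraint force telescopes to zero for any multipliers."""
        params = PhysicalParams.reference()
        rng = np.random.default_rng(seed)
        state = bent_swimmer(params, rng, n_flag=8)
        Lam = rng.normal(scale=100.0, size=(8, 3))
        F, _ = sw.constraint_forces(state, Lam, rng.normal(), params)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)


class TestQuaternions:
    def test_unit_norm_and_tangent_consistency(self, params, rng):
        state = bent_swimmer(params, rng)
        q = state.quaternions
        assert np.allclose(np.linalg.norm(q, axis=-1), 1.0, atol=1e-12)
        # tangent is the rotated body x-axis
        w, z = q[:, 0], q[:, 3]
        tx = w * w - z * z
        ty = 2 * w * z
        assert np.allclose(np.stack([tx, ty], axis=-1),
                           state.t_hat[:, :2], atol=1e-12)
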
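"""Analysis statistics: moments, order parameters, spectra, clusters."""

import numpy as np
import pytest

from spermflow import observables as obs


class TestForceMoments:
    def test_point_force_at_com_has_no_moments(self):
        D, Q = obs.force_moments([[1.0, 2.0]], [[5.0, 5.0]], [5.0, 5.0],
                                 [1.0, 0.0])
        assert np.allclose(D, 0.0) and np.allclose(Q, 0.0)

    def test_pusher_pair_dipole(self):
        """-F x at +h/2 x and +F x at -h/2 x give G11 = -F h."""
        F, h = 2.0, 3.0
        forces = [[-F, 0.0], [F, 0.0]]
        pos = [[h / 2, 0.0], [-h / 2, 0.0]]
        ms = obs.moment_series([0.0], [forces], [pos], [[0.0, 0.0]],
                               [1.0, 0.0], F0=None, d=1.0)
        D11_raw = -F * h
        # after removing the trace: G11 = D11 - D11/3
        assert ms.G[0, 0, 0] == pytest.approx(D11_raw * 2 / 3)
        assert ms.G[0, 1, 1] == pytest.approx(-D11_raw / 3)
        assert np.allclose(ms.D_A[0], 0.0)
        assert np.trace(ms.G[0]) == pytest.approx(0.0, abs=1e-12)

    def test_frame_rotation_equivariance(self, rng):
        """Rotating the lab system and the frame together leaves the
        swimmer-frame moments unchanged."""
        forces = rng.normal(size=(5, 2))
        forces -= forces.mean(axis=0)          # force-free
        pos = rng.normal(size=(5, 2))
        com = pos.mean(axis=0)
        alpha = 1.1
        R = np.array([[np.cos(alpha), -np.sin(alpha)],
                      [np.sin(alpha), np.cos(alpha)]])
        a = obs.force_moments(forces, pos, com, [1.0, 0.0])
        b = obs.force_moments(forces @ R.T, pos @ R.T, R @ com, R @ [1, 0])
        assert np.allclose(a[0], b[0], atol=1e-12)
        assert np.allclose(a[1], b[1], atol=1e-12)

    def test_torque_free_swimmer_zero_antisymmetric_dipole(self, rng):
        """Forces from internal interactions: sum F = 0 and sum r x F = 0
        imply the antisymmetric dipole vanishes."""
        pos = rng.normal(size=(6, 2))
        f = rng.normal(size=(6, 2))
        f -= f.mean(axis=0)
        # remove net torque by adding a rigid correction field
        r = pos - pos.mean(axis=0)
        tau = np.sum(r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0])
        I = np.sum(r ** 2)
        f += tau / I * np.stack([r[:, 1], -r[:, 0]], axis=-1)
        ms = obs.moment_series([0.0], [f], [pos], [pos.mean(axis=0)],
                               [1.0, 0.0], F0=None, d=1.0)
        assert np.max(np.abs(ms.D_A)) < 1e-10

    def test_f0_linearity_and_errors(self):
        class FakeBackend:
            def self_mobility(self, kind):
                return 0.01, 0.001
        assert obs.f0_normalization(2.0, FakeBackend()) == \
            2 * obs.f0_normalization(1.0, FakeBackend())
        with pytest.raises(ValueError):
            obs.f0_normalization(0.0, FakeBackend())


class TestCrossover:
    def _ms(self, G11, K111):
        n = len(G11)
        ms = obs.MomentSet(
            t=np.arange(n, dtype=float), G=np.zeros((n, 3, 3)),
            D_A=np.zeros((n, 3, 3)), K_S=np.zeros((n, 3, 3, 3)),
            K_A=np.zeros((n, 3, 3, 3)), F0=1.0, d=1.0)
        ms.G[:, 0, 0] = G11
        ms.K_S[:, 0, 0, 0] = K111
        return ms

    def test_printed_ratio_arithmetic(self):
        """Max dipole 5.5 x |mean|, max quadrupole 7 x |mean| -> r* ~ 2.8d."""
        ms = self._ms([5.5 * 1.050e-3], [7 * 2.321e-3])
        assert obs.singularity_crossover(ms) == pytest.approx(2.81, abs=0.02)

    def test_zero_quadrupole(self):
        ms = self._ms([1.0, -2.0], [0.0, 0.0])
        assert obs.singularity_crossover(ms) == 0.0

    def test_homogeneity(self):
        a = obs.singularity_crossover(self._ms([1.0], [2.0]))
        b = obs.singularity_crossover(self._ms([1.0], [4.0]))
        assert b == pytest.approx(2 * a)

    def test_zero_dipole_rejected(self):
        with pytest.raises(ValueError):
            obs.singularity_crossover(self._ms([0.0], [1.0]))


class TestOrderParameters:
    def test_perfect_polar_state(self):
        p = np.tile([[-1.0, 0.0]], (20, 1))[None]
        s = obs.order_parameters([0.0], p, [-1.0, 0.0])
        assert s.S1[0] == pytest.approx(1.0)
        assert s.S2[0] == pytest.approx(1.0)

    def test_perpendicular_split(self):
        p = np.array([[[0.0, 1.0]] * 5 + [[0.0, -1.0]] * 5])
        s = obs.order_parameters([0.0], p, [-1.0, 0.0])
        assert s.S1[0] == pytest.approx(0.0, abs=1e-15)
        assert s.S2[0] == pytest.approx(-1.0)

    def test_isotropic_limits(self):
        """|S1|, |S2| <= 3/sqrt(N) for random planar orientations."""
        rng = np.random.default_rng(11)
        N = 10 ** 4
        ang = rng.uniform(0, 2 * np.pi, N)
        p = np.stack([np.cos(ang), np.sin(ang)], axis=-1)[None]
        s = obs.order_parameters([0.0], p, [-1.0, 0.0])
        assert abs(s.S1[0]) <= 3 / np.sqrt(N)
        assert abs(s.S2[0]) <= 3 / np.sqrt(N)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            obs.order_parameters([0.0], np.array([[[2.0, 0.0]]]),
                                 [1.0, 0.0])

    def test_mean_orientation_filters_wobble(self):
        t = np.arange(300)
        base = np.stack([np.ones(300), 0.3 * np.sin(2 * np.pi * t / 100)],
                        axis=-1)[:, None, :]
        p = obs.mean_orientations(base, 100)
        assert np.max(np.abs(p[:, 0, 1])) < 0.02


class TestSpectra:
    def test_single_mode_parseval(self):
        """u = A sin(k0 x) y: all energy in the k0 shell, total A^2/4."""
        n, L, A = 64, 10.0, 1.7
        x = np.arange(n) * L / n
        u = np.zeros((2, n, n))
        k0_index = 3
        u[1] = A * np.sin(2 * np.pi * k0_index * x / L)[:, None]
        spec = obs.energy_spectrum(u, L)
        total = spec.S_k.sum()
        assert total == pytest.approx(A ** 2 / 4, rel=1e-12)
        assert spec.S_k[k0_index] == pytest.approx(total, rel=1e-12)

    def test_zero_field(self):
        spec = obs.energy_spectrum(np.zeros((2, 32, 32)), 5.0)
        assert not spec.S_k.any()

    def test_parseval_random_field(self, rng):
        u = rng.normal(size=(3, 2, 48, 48))
        spec = obs.energy_spectrum(u, 7.0)
        grid_energy = 0.5 * np.mean(np.sum(u ** 2, axis=1), axis=(1, 2))
        assert spec.S_k.sum() == pytest.approx(grid_energy.mean(),
                                               rel=1e-8)


class TestLowpass:
    def test_constant_series_unchanged(self):
        out = obs.lowpass_filter(np.full(100, 2.5), 16)
        assert np.allclose(out, 2.5)
        assert len(out) == 100 - 16 + 1

    def test_oscillation_attenuated(self):
        """A pure tone of period T is suppressed by an 8T running mean."""
        spp = 40                      # samples per period
        t = np.arange(2000)
        sig = np.cos(2 * np.pi * t / spp)
        out = obs.lowpass_filter(sig, 8 * spp)
        # moving-average transfer: |sinc(8)| = 0 for an integer window
        assert np.max(np.abs(out)) < 0.05

    def test_linearity(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        la = obs.lowpass_filter(a, 25)
        lb = obs.lowpass_filter(b, 25)
        lab = obs.lowpass_filter(2 * a - 3 * b, 25)
        assert np.allclose(lab, 2 * la - 3 * lb, atol=1e-12)

    def test_window_bounds(self):
        with pytest.raises(ValueError):
            obs.lowpass_filter(np.ones(10), 11)


class TestComSpectrum:
    def test_uniform_motion_concentrates_at_large_scales(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 100.0, size=(1, 30, 2))
        U = np.tile([[0.5, 0.0]], (30, 1))[None]
        spec = obs.com_velocity_spectrum(X, U, L=100.0, n_grid=64,
                                         kernel_width=17.0)
        low = spec.S_k[:4].sum()
        assert low > 0.9 * spec.S_k.sum()

    def test_single_swimmer_kernel_transform(self):
        """One deposited kernel: spectrum follows the Gaussian envelope."""
        L, ngrid, w = 100.0, 128, 5.0
        X = np.array([[[50.0, 50.0]]])
        U = np.array([[[1.0, 0.0]]])
        spec = obs.com_velocity_spectrum(X, U, L=L, n_grid=ngrid,
                                         kernel_width=w)
        # normalized deposition -> unit plateau near the particle; energy
        # concentrated below k ~ 1/w
        k_half = 1.0 / w
        sel = spec.k < k_half
        assert spec.S_k[sel].sum() > 0.8 * spec.S_k.sum()

    def test_no_swimmers_rejected(self):
        with pytest.raises(ValueError):
            obs.com_velocity_spectrum(np.zeros((1, 0, 2)),
                                      np.zeros((1, 0, 2)), L=10.0,
                                      n_grid=16, kernel_width=1.0)


class TestClusters:
    def test_all_isolated(self):
        pos = np.zeros((4, 2, 2))
        for s in range(4):
            pos[s] += 40.0 * s
        p = np.tile([1.0, 0.0], (4, 1))
        sizes = obs.cluster_sizes(pos, p, L=400.0, distance_cut=3.0,
                                  align_cut=np.cos(np.radians(30)))
        assert list(sizes) == [1, 1, 1, 1]

    def test_touching_aligned_pair(self):
        pos = np.zeros((2, 2, 2))
        pos[1, :, 1] = 1.0
        p = np.tile([1.0, 0.0], (2, 1))
        sizes = obs.cluster_sizes(pos, p, L=50.0, distance_cut=3.0,
                                  align_cut=np.cos(np.radians(30)))
        assert list(sizes) == [2]

    def test_misaligned_contact_not_linked(self):
        pos = np.zeros((2, 2, 2))
        pos[1, :, 1] = 1.0
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        sizes = obs.cluster_sizes(pos, p, L=50.0, distance_cut=3.0,
                                  align_cut=np.cos(np.radians(30)))
        assert list(sizes) == [1, 1]

    def test_matches_bruteforce_components(self, rng):
        S, B, L = 12, 3, 120.0
        pos = rng.uniform(0, L, size=(S, 1, 2)) + \
            rng.normal(scale=1.0, size=(S, B, 2))
        ang = rng.uniform(0, 2 * np.pi, S)
        p = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        cut, ac = 6.0, np.cos(np.radians(30))
        sizes = obs.cluster_sizes(pos, p, L=L, distance_cut=cut,
                                  align_cut=ac)

        # O(S^2 B^2) reference
        adj = np.zeros((S, S), dtype=bool)
        for a in range(S):
            for b in range(a + 1, S):
                d = pos[a][:, None, :] - pos[b][None, :, :]
                d -= L * np.round(d / L)
                dm = np.sqrt((d ** 2).sum(-1)).min()
                if dm < cut and p[a] @ p[b] > ac:
                    adj[a, b] = adj[b, a] = True
        seen = np.zeros(S, dtype=bool)
        ref = []
        for s in range(S):
            if seen[s]:
                continue
            stack, comp = [s], 0
            seen[s] = True
            while stack:
                u = stack.pop()
                comp += 1
                for v in np.nonzero(adj[u])[0]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            ref.append(comp)
        assert sorted(sizes.tolist()) == sorted(ref)
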
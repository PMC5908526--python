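"""Force-coupling method (FCM) on a periodic grid.

Bodies are represented by Gaussian force envelopes.  A body of hydrodynamic
radius ``a`` spreads its force with the monopole envelope

    Delta(r)   = (2 pi sigma^2)^(-3/2) exp(-r^2 / 2 sigma^2),   sigma = a / sqrt(pi)

and its torque as the antisymmetric (rotlet) dipole of a narrower Gaussian
with sigma_d = a / (6 sqrt(pi))^(1/3).  These widths make the isolated
translational and rotational drags of the particle match 6 pi eta a U and
8 pi eta a^3 W analytically.  The Stokes equations are solved spectrally in
the triply periodic box, and body velocities/angular velocities are read
back by averaging the fluid velocity (and half its curl) against the same
envelopes — the adjoint of spreading, which makes the grand mobility
symmetric positive-semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..params import GridSpec

__all__ = ["FluidField", "sigma_monopole", "sigma_dipole", "fcm_spread",
           "stokes_solve_periodic", "fcm_interpolate", "fcm_mobility"]

_SUPPORT_SIGMAS = 8.0  # Gaussian truncation radius in units of sigma


def sigma_monopole(a) -> np.ndarray:
    return np.asarray(a, dtype=float) / np.sqrt(np.pi)


def sigma_dipole(a) -> np.ndarray:
    return np.asarray(a, dtype=float) / (6.0 * np.sqrt(np.pi)) ** (1.0 / 3.0)


@dataclass
class FluidField:
    """Velocity and/or force-density fields on the periodic grid.

    Arrays have shape (3, N_x, N_y, N_z).
    """

    grid: GridSpec
    u: np.ndarray | None = None
    f_grid: np.ndarray | None = None

    def k_mesh(self):
        """Sparse wavevector mesh with Nyquist modes zeroed.

        Odd (derivative-like) spectral operators are ill-defined at the
        Nyquist wavenumber of a real transform; zeroing it there keeps the
        Hermitian symmetry of projected fields exact.
        """
        g = self.grid
        kx = 2.0 * np.pi * np.fft.fftfreq(g.N_x, d=g.dx)
        ky = 2.0 * np.pi * np.fft.fftfreq(g.N_y, d=g.dx)
        kz = 2.0 * np.pi * np.fft.rfftfreq(g.N_z, d=g.dx)
        kx[g.N_x // 2] = 0.0
        ky[g.N_y // 2] = 0.0
        kz[-1] = 0.0
        return np.meshgrid(kx, ky, kz, indexing="ij", sparse=True)

    def k2_full(self):
        """|k|^2 with the full (unzeroed) Nyquist magnitudes, for eta k^2."""
        g = self.grid
        kx = 2.0 * np.pi * np.fft.fftfreq(g.N_x, d=g.dx)
        ky = 2.0 * np.pi * np.fft.fftfreq(g.N_y, d=g.dx)
        kz = 2.0 * np.pi * np.fft.rfftfreq(g.N_z, d=g.dx)
        kxm, kym, kzm = np.meshgrid(kx, ky, kz, indexing="ij", sparse=True)
        return kxm ** 2 + kym ** 2 + kzm ** 2

    def divergence_norm(self) -> float:
        """Spectral norm of div(u) relative to ||grad u||-scale of u."""
        kxm, kym, kzm = self.k_mesh()
        uh = [np.fft.rfftn(self.u[i]) for i in range(3)]
        div = 1j * (kxm * uh[0] + kym * uh[1] + kzm * uh[2])
        kk = np.sqrt(kxm ** 2 + kym ** 2 + kzm ** 2)
        scale = np.sqrt(sum(np.sum(np.abs(kk * u) ** 2) for u in uh))
        return float(np.sqrt(np.sum(np.abs(div) ** 2)) / max(scale, 1e-300))


def _support_slices(center: np.ndarray, sigma: float, grid: GridSpec):
    """Index arrays (mod N) and coordinates of the Gaussian support patch."""
    dx = grid.dx
    w = int(np.ceil(_SUPPORT_SIGMAS * sigma / dx))
    out = []
    for c, n in zip(center, grid.shape):
        i0 = int(np.floor(c / dx))
        idx = np.arange(i0 - w, i0 + w + 1)
        out.append((idx % n, idx * dx - c))
    return out


def fcm_spread(positions, radii, F=None, T=None, *,
               grid: GridSpec) -> FluidField:
    """Deposit body forces/torques as a force-density field on the grid.

    ``positions`` (P, 3), ``radii`` (P,) hydrodynamic radii, ``F`` (P, 3)
    forces, ``T`` (P, 3) torques (either may be None).  The envelope must
    be resolved: sigma/dx >= 1.5.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), positions.shape[:1])
    sig = sigma_monopole(radii)
    if np.min(sig) / grid.dx < 1.5 - 1e-9:
        raise ValueError(
            f"unresolved envelope: sigma/dx = {np.min(sig) / grid.dx:.3f} < 1.5")

    f = np.zeros((3,) + grid.shape)
    for p in range(positions.shape[0]):
        if F is not None and np.any(F[p]):
            s = float(sig[p])
            (ix, rx), (iy, ry), (iz, rz) = _support_slices(positions[p], s, grid)
            gx = np.exp(-rx ** 2 / (2 * s * s))
            gy = np.exp(-ry ** 2 / (2 * s * s))
            gz = np.exp(-rz ** 2 / (2 * s * s))
            blob = (2 * np.pi * s * s) ** -1.5 * \
                gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
            for c in range(3):
                np.add.at(f[c], np.ix_(ix, iy, iz), F[p][c] * blob)
        if T is not None and np.any(T[p]):
            sd = float(sigma_dipole(radii[p]))
            (ix, rx), (iy, ry), (iz, rz) = _support_slices(positions[p], sd, grid)
            gx = np.exp(-rx ** 2 / (2 * sd * sd))
            gy = np.exp(-ry ** 2 / (2 * sd * sd))
            gz = np.exp(-rz ** 2 / (2 * sd * sd))
            blob = (2 * np.pi * sd * sd) ** -1.5 * \
                gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
            # f = (1/2) grad(Delta_d) x T = (Delta_d / 2 sigma_d^2) T x r
            rxg = rx[:, None, None]
            ryg = ry[None, :, None]
            rzg = rz[None, None, :]
            pref = blob / (2.0 * sd * sd)
            Tp = T[p]
            np.add.at(f[0], np.ix_(ix, iy, iz), pref * (Tp[1] * rzg - Tp[2] * ryg))
            np.add.at(f[1], np.ix_(ix, iy, iz), pref * (Tp[2] * rxg - Tp[0] * rzg))
            np.add.at(f[2], np.ix_(ix, iy, iz), pref * (Tp[0] * ryg - Tp[1] * rxg))
    return FluidField(grid=grid, f_grid=f)


def stokes_solve_periodic(field: FluidField, *, eta: float = 1.0,
                          remove_mean: bool = True,
                          mean_force_rtol: float = 1e-8) -> FluidField:
    """Solve eta lap(u) = -f, div(u) = 0 in the periodic box, spectrally.

    Swimmer systems are force free, so the k = 0 mode of the force density
    should vanish up to round-off.  With ``remove_mean=True`` (default) any
    mean force is dropped — the standard periodic convention in which a net
    force is balanced by a uniform pressure gradient, as required e.g. for
    the Hasimoto drag of a single dragged sphere.  With
    ``remove_mean=False`` a genuinely non-zero mean force is rejected.
    """
    f = field.f_grid
    grid = field.grid
    if not remove_mean:
        mean_f = f.mean(axis=(1, 2, 3))
        scale = np.max(np.abs(f)) + 1e-300
        if np.max(np.abs(mean_f)) > mean_force_rtol * scale:
            raise ValueError("force density has a non-zero mean; periodic "
                             "Stokes problem is unsolvable")
    kxm, kym, kzm = field.k_mesh()
    k2p = kxm ** 2 + kym ** 2 + kzm ** 2      # projection scale (Nyquist 0)
    k2p[k2p == 0.0] = 1.0
    k2 = field.k2_full()
    k2[0, 0, 0] = 1.0
    fh = [np.fft.rfftn(f[i]) for i in range(3)]
    kdotf = kxm * fh[0] + kym * fh[1] + kzm * fh[2]
    u = np.empty_like(f)
    for i, km in enumerate((kxm, kym, kzm)):
        uh = (fh[i] - km * kdotf / k2p) / (eta * k2)
        uh[0, 0, 0] = 0.0
        u[i] = np.fft.irfftn(uh, s=grid.shape)
    return FluidField(grid=grid, u=u, f_grid=f)


def _gauss_weights(center, sigma, grid):
    (ix, rx), (iy, ry), (iz, rz) = _support_slices(center, sigma, grid)
    gx = np.exp(-rx ** 2 / (2 * sigma * sigma))
    gy = np.exp(-ry ** 2 / (2 * sigma * sigma))
    gz = np.exp(-rz ** 2 / (2 * sigma * sigma))
    blob = (2 * np.pi * sigma ** 2) ** -1.5 * \
        gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return (ix, iy, iz), blob


def fcm_interpolate(field: FluidField, positions, radii, *,
                    want_angular: bool = True):
    """Average the solved flow over the body envelopes.

    Returns (U, W): U_n = int u Delta_n dV and, if requested,
    W_n = (1/2) int (curl u) Delta_d,n dV with the curl evaluated
    spectrally.  This is the adjoint of ``fcm_spread`` (reciprocity).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), positions.shape[:1])
    grid = field.grid
    dV = grid.dx ** 3
    u = field.u

    curl = None
    if want_angular:
        kxm, kym, kzm = field.k_mesh()
        uh = [np.fft.rfftn(u[i]) for i in range(3)]
        curl = np.empty_like(u)
        curl[0] = np.fft.irfftn(1j * (kym * uh[2] - kzm * uh[1]), s=grid.shape)
        curl[1] = np.fft.irfftn(1j * (kzm * uh[0] - kxm * uh[2]), s=grid.shape)
        curl[2] = np.fft.irfftn(1j * (kxm * uh[1] - kym * uh[0]), s=grid.shape)

    P = positions.shape[0]
    U = np.zeros((P, 3))
    W = np.zeros((P, 3))
    for p in range(P):
        (ix, iy, iz), blob = _gauss_weights(
            positions[p], float(sigma_monopole(radii[p])), grid)
        patch = np.ix_(ix, iy, iz)
        for c in range(3):
            U[p, c] = np.sum(u[c][patch] * blob) * dV
        if want_angular:
            (ix, iy, iz), blob = _gauss_weights(
                positions[p], float(sigma_dipole(radii[p])), grid)
            patch = np.ix_(ix, iy, iz)
            for c in range(3):
                W[p, c] = 0.5 * np.sum(curl[c][patch] * blob) * dV
    return (U, W) if want_angular else (U, None)


def fcm_mobility(positions, radii, F=None, T=None, *, grid: GridSpec,
                 eta: float = 1.0, want_angular: bool = True):
    """Spread -> periodic Stokes solve -> interpolate.

    The composed map (F, T) -> (U, W) is linear, symmetric and
    positive-semidefinite (energy dissipation: sum F.U + sum T.W >= 0).
    """
    field = fcm_spread(positions, radii, F, T, grid=grid)
    solved = stokes_solve_periodic(field, eta=eta)
    return fcm_interpolate(solved, positions, radii,
                           want_angular=want_angular)
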
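"""Analysis statistics: flow force moments, order parameters, spectra.

The far field of a swimmer is organized by the moments of the force
distribution it exerts on the fluid.  With r measured from the swimmer's
centre of mass in the swimmer frame (x along the mean swimming direction,
z the film normal), the raw moments are

    D_ij  = sum_n F_i^(n) r_j^(n)               (dipole)
    Q_ijk = sum_n F_i^(n) r_j^(n) r_k^(n)       (quadrupole)

G is the symmetric-traceless part of D (the stresslet; its antisymmetric
part vanishes for a torque-free swimmer), K^S the part of Q symmetric and
traceless in the first two indices, and K^A the antisymmetric part.
Moments are reported in units of F0 d and F0 d^2, where F0 is the in-plane
drag of the isolated head translating at the mean swimming speed, computed
with the same mobility solver as the simulation.

Spectra: the fluid energy spectrum S(k) sums (1/2)|u_hat|^2 over in-plane
wavevector shells of width 2 pi / L, so that sum_k S(k) equals the mean
kinetic-energy density functional of the midplane flow (Parseval).  The
swimmer centre-of-mass velocity field is deposited on a 2D grid with a
Gaussian kernel before the same shell average.  A running time average of
width 8 T (low-pass) removes the undulation time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MomentSet", "SpectrumSet", "OrderParamSeries",
    "force_moments", "moment_series", "f0_normalization",
    "singularity_crossover", "order_parameters", "mean_orientations",
    "energy_spectrum", "lowpass_filter", "com_velocity_spectrum",
    "cluster_sizes",
]


# ---------------------------------------------------------------------------
# force moments


def _frame_matrix(e_x) -> np.ndarray:
    """Right-handed frame with x along ``e_x`` (in-plane) and z the normal."""
    e_x = np.asarray(e_x, dtype=float)
    if e_x.shape == (2,):
        e_x = np.array([e_x[0], e_x[1], 0.0])
    n = np.linalg.norm(e_x)
    if n == 0:
        raise ValueError("frame axis must be non-zero")
    ex = e_x / n
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.cross(ez, ex)
    return np.stack([ex, ey, ez])


def _pad3(arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape[-1] == 2:
        arr = np.concatenate([arr, np.zeros(arr.shape[:-1] + (1,))], axis=-1)
    return arr


def force_moments(forces, positions, com, e_x):
    """One sample of the raw dipole and quadrupole tensors.

    ``forces`` are the forces the bodies exert ON the fluid (the negative
    of the hydrodynamic drag on the bodies).  Returns (D, Q) in the
    swimmer frame; split into G/K^S/K^A with :func:`moment_series`.
    """
    R = _frame_matrix(e_x)
    F = _pad3(forces) @ R.T
    r = (_pad3(positions) - _pad3(np.atleast_1d(com))) @ R.T
    D = np.einsum("ni,nj->ij", F, r)
    Q = np.einsum("ni,nj,nk->ijk", F, r, r)
    return D, Q


def _split_dipole(D):
    sym = 0.5 * (D + np.swapaxes(D, -1, -2))
    tr = np.trace(sym, axis1=-2, axis2=-1)
    G = sym - tr[..., None, None] / 3.0 * np.eye(3)
    antisym = 0.5 * (D - np.swapaxes(D, -1, -2))
    return G, antisym


def _split_quadrupole(Q):
    KS = 0.5 * (Q + np.swapaxes(Q, -3, -2))
    tr = np.einsum("...iik->...k", KS)
    KS = KS - np.einsum("ij,...k->...ijk", np.eye(3) / 3.0, tr)
    KA = 0.5 * (Q - np.swapaxes(Q, -3, -2))
    return KS, KA


@dataclass
class MomentSet:
    """Time series of swimmer force moments, normalized by F0 d (F0 d^2)."""

    t: np.ndarray
    G: np.ndarray            # (n, 3, 3)
    D_A: np.ndarray          # antisymmetric dipole part, should vanish
    K_S: np.ndarray          # (n, 3, 3, 3)
    K_A: np.ndarray
    F0: float | None
    d: float

    @property
    def G11(self) -> np.ndarray:
        return self.G[:, 0, 0]

    @property
    def G22(self) -> np.ndarray:
        return self.G[:, 1, 1]

    @property
    def K111(self) -> np.ndarray:
        return self.K_S[:, 0, 0, 0]

    @property
    def K221(self) -> np.ndarray:
        return self.K_S[:, 1, 1, 0]


def moment_series(t, forces, positions, coms, e_x, *, torques_z=None,
                  F0=None, d: float = 1.0) -> MomentSet:
    """Moment tensors for a whole trajectory of one swimmer.

    ``forces``/``positions``: (n, P, 2 or 3) per-sample body data; ``coms``
    (n, 2 or 3); ``e_x`` the mean swimming direction defining the frame.
    ``torques_z`` (n, P), the out-of-plane body torques, adds the moment
    contributions of the rotlet (point-torque) part of the force system:
    a torque T at r0 carries the antisymmetric dipole -eps_ijk T_k / 2 and
    the quadrupole -(eps_ijm r0_k + eps_ikm r0_j) T_m / 2.  With them the
    antisymmetric dipole of a torque-free swimmer vanishes identically.
    When ``F0`` is None the output is unnormalized and flagged as such by
    the attribute itself.
    """
    n = len(t)
    D = np.empty((n, 3, 3))
    Q = np.empty((n, 3, 3, 3))
    for i in range(n):
        D[i], Q[i] = force_moments(forces[i], positions[i], coms[i], e_x)
    if torques_z is not None:
        R = _frame_matrix(e_x)
        Tz = np.asarray(torques_z, dtype=float)        # invariant under R
        for i in range(n):
            r = (_pad3(positions[i]) - _pad3(coms[i])) @ R.T
            Ts = Tz[i].sum()
            D[i, 0, 1] -= 0.5 * Ts
            D[i, 1, 0] += 0.5 * Ts
            m1 = 0.5 * (Tz[i][:, None] * r).sum(axis=0)   # (3,)
            Q[i, 0, 1, :] -= m1
            Q[i, 0, :, 1] -= m1
            Q[i, 1, 0, :] += m1
            Q[i, 1, :, 0] += m1
    G, D_A = _split_dipole(D)
    K_S, K_A = _split_quadrupole(Q)
    scale1 = (F0 * d) if F0 else 1.0
    scale2 = (F0 * d * d) if F0 else 1.0
    return MomentSet(t=np.asarray(t, dtype=float), G=G / scale1,
                     D_A=D_A / scale1, K_S=K_S / scale2, K_A=K_A / scale2,
                     F0=F0, d=d)


def f0_normalization(U_mean: float, backend, *, head_kind: int = 1) -> float:
    """In-plane drag of the isolated head moving at the mean swimming speed.

    Uses the translational self-mobility of the head from the same
    mobility backend as the simulation (periodic-box correction included).
    """
    if U_mean == 0 or not np.isfinite(U_mean):
        raise ValueError("mean swimming speed must be finite and non-zero")
    M = backend.self_mobility(head_kind)[0]
    return float(abs(U_mean) / M)


def singularity_crossover(moments: MomentSet, *, use_components=True) -> float:
    """Separation below which the quadrupolar flow beats the dipolar flow.

    From far-field scaling |u_quad|/|u_dip| ~ (K/G)/r, the crossover is
    r* = max_t |K| / max_t |G|, reported in units of the swimmer length d.
    By default the dominant components (G11, K111) are compared.
    """
    if use_components:
        gmax = float(np.max(np.abs(moments.G11)))
        kmax = float(np.max(np.abs(moments.K111)))
    else:
        gmax = float(np.max(np.linalg.norm(moments.G, axis=(1, 2))))
        kmax = float(np.max(np.sqrt(np.sum(moments.K_S ** 2, axis=(1, 2, 3)))))
    if gmax == 0.0:
        raise ValueError("dipole series vanishes; crossover undefined")
    # moments are stored in units of F0 d and F0 d^2, so the ratio is in d
    return kmax / gmax


# ---------------------------------------------------------------------------
# order parameters


@dataclass
class OrderParamSeries:
    t: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    p_hat: np.ndarray        # (n, N, 2)


def mean_orientations(head_tail: np.ndarray,
                      samples_per_period: int | None = None) -> np.ndarray:
    """Per-swimmer mean orientation from the head-minus-tail axis.

    ``head_tail`` has shape (n, N, 2).  A centred moving average over one
    undulation period removes the wobble of the end-to-end axis before
    normalization; pass None to skip filtering.
    """
    p = np.asarray(head_tail, dtype=float)
    if samples_per_period and len(p) >= samples_per_period:
        p = _moving_average(p, samples_per_period)
    norm = np.linalg.norm(p, axis=-1, keepdims=True)
    return p / np.maximum(norm, 1e-300)


def order_parameters(t, p_hat, e0) -> OrderParamSeries:
    """Polar and planar-nematic order with respect to ``e0``.

    S1(t) = <p_n . e0>_n,  S2(t) = <2 (p_n . e0)^2 - 1>_n.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    norms = np.linalg.norm(p_hat, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("orientations must be unit vectors")
    e0 = np.asarray(e0, dtype=float)
    e0 = e0 / np.linalg.norm(e0)
    c = p_hat @ e0
    return OrderParamSeries(t=np.asarray(t, dtype=float),
                            S1=c.mean(axis=-1),
                            S2=(2.0 * c * c - 1.0).mean(axis=-1),
                            p_hat=p_hat)


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumSet:
    """Shell-summed in-plane spectrum with sampling statistics."""

    k: np.ndarray            # shell centres
    S_k: np.ndarray          # time-averaged shell sums of (1/2)|u_hat|^2
    sd: np.ndarray           # sample standard deviation over snapshots
    n_modes: np.ndarray      # modes per shell

    def slope(self, k_lo: float, k_hi: float) -> float:
        """Log-log slope fitted over k in [k_lo, k_hi]."""
        m = (self.k >= k_lo) & (self.k <= k_hi) & (self.S_k > 0)
        if np.count_nonzero(m) < 3:
            raise ValueError("not enough shells in the fit window")
        return float(np.polyfit(np.log(self.k[m]), np.log(self.S_k[m]), 1)[0])


def _shell_bins(nx, ny, L):
    kx = 2.0 * np.pi * np.fft.fftfreq(nx) * nx / L
    ky = 2.0 * np.pi * np.fft.fftfreq(ny) * ny / L
    kk = np.sqrt(kx[:, None] ** 2 + ky[None, :] ** 2)
    dk = 2.0 * np.pi / L
    idx = np.rint(kk / dk).astype(int)
    return idx, dk


def energy_spectrum(u_snaps, L: float) -> SpectrumSet:
    """Shell-summed energy spectrum of midplane velocity snapshots.

    ``u_snaps`` has shape (n_t, 2, N, N) (a single snapshot may omit the
    leading axis).  The transform is normalized so that
    sum_k S(k) = <(1/2)|u|^2>_grid per snapshot.
    """
    u = np.asarray(u_snaps, dtype=float)
    if u.ndim == 3:
        u = u[None]
    nt, nc, nx, ny = u.shape
    idx, dk = _shell_bins(nx, ny, L)
    nshell = idx.max() + 1
    samples = np.empty((nt, nshell))
    for it in range(nt):
        E = np.zeros((nx, ny))
        for c in range(nc):
            uh = np.fft.fft2(u[it, c]) / (nx * ny)
            E += 0.5 * np.abs(uh) ** 2
        samples[it] = np.bincount(idx.ravel(), weights=E.ravel(),
                                  minlength=nshell)
    n_modes = np.bincount(idx.ravel(), minlength=nshell)
    return SpectrumSet(
        k=dk * np.arange(nshell), S_k=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=1) if nt > 1 else np.zeros(nshell),
        n_modes=n_modes)


def _moving_average(series, window: int):
    s = np.asarray(series, dtype=float)
    c = np.cumsum(s, axis=0)
    out = np.empty((s.shape[0] - window + 1,) + s.shape[1:])
    out[0] = c[window - 1] / window
    out[1:] = (c[window:] - c[:-window]) / window
    return out


def lowpass_filter(series, window: int):
    """Centred running mean of integer width ``window`` along axis 0.

    Used with window = 8 T / dt_snapshot to suppress the undulation time
    scale.  The output is shorter by window - 1 samples; the operator is
    linear and leaves constants unchanged.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window > series.shape[0]:
        raise ValueError("window must be between 1 and the series length")
    return _moving_average(series, window)


def com_velocity_spectrum(X_cm, U_cm, *, L: float, n_grid: int,
                          kernel_width: float) -> SpectrumSet:
    """Spectrum of the swimmer centre-of-mass velocity field.

    Velocities are deposited on an ``n_grid`` x ``n_grid`` periodic grid
    with a normalized Gaussian kernel of the given width (d/4 by default
    in callers); cells with no nearby swimmer stay zero.  The result has a
    noise floor at sub-flagellum scales set by the deposition itself.
    """
    X = np.asarray(X_cm, dtype=float)
    U = np.asarray(U_cm, dtype=float)
    if X.ndim == 2:
        X, U = X[None], U[None]
    nt, N, _ = X.shape
    if N == 0:
        raise ValueError("no swimmers")
    dxg = L / n_grid
    w = max(int(np.ceil(4.0 * kernel_width / dxg)), 2)
    snaps = np.zeros((nt, 2, n_grid, n_grid))
    for it in range(nt):
        num = np.zeros((2, n_grid, n_grid))
        den = np.zeros((n_grid, n_grid))
        for m in range(N):
            i0 = int(np.floor(X[it, m, 0] / dxg))
            j0 = int(np.floor(X[it, m, 1] / dxg))
            ii = np.arange(i0 - w, i0 + w + 1)
            jj = np.arange(j0 - w, j0 + w + 1)
            gx = np.exp(-(ii * dxg - X[it, m, 0]) ** 2 /
                        (2 * kernel_width ** 2))
            gy = np.exp(-(jj * dxg - X[it, m, 1]) ** 2 /
                        (2 * kernel_width ** 2))
            blob = gx[:, None] * gy[None, :]
            sel = np.ix_(ii % n_grid, jj % n_grid)
            den[sel] += blob
            num[0][sel] += U[it, m, 0] * blob
            num[1][sel] += U[it, m, 1] * blob
        mask = den > 1e-12
        for c in range(2):
            snaps[it, c][mask] = num[c][mask] / den[mask]
    return energy_spectrum(snaps, L)


# ---------------------------------------------------------------------------
# clustering


def cluster_sizes(body_positions, p_hat, *, L: float, distance_cut: float,
                  align_cut: float) -> np.ndarray:
    """Sizes of aligned contact clusters, sorted descending.

    Swimmers are linked when their minimum body-body distance is below
    ``distance_cut`` and their mean orientations satisfy
    p_i . p_j > align_cut; cluster sizes are the connected components of
    that graph.  This aggregation metric quantifies the cluster-forming
    versus turbulence-like states of the suspension.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    pos = np.asarray(body_positions, dtype=float)   # (S, B, 2)
    S, B, _ = pos.shape
    p_hat = np.asarray(p_hat, dtype=float)
    flat = np.mod(pos.reshape(-1, 2), L)
    tree = cKDTree(flat, boxsize=L)
    pairs = tree.query_pairs(distance_cut, output_type="ndarray")
    if pairs.size:
        si = pairs[:, 0] // B
        sj = pairs[:, 1] // B
        diff = si != sj
        align = np.einsum("ij,ij->i", p_hat[si], p_hat[sj]) > align_cut
        keep = diff & align
        si, sj = si[keep], sj[keep]
    else:
        si = sj = np.empty(0, dtype=int)
    adj = coo_matrix((np.ones(len(si)), (si, sj)), shape=(S, S))
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return np.sort(sizes)[::-1]
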
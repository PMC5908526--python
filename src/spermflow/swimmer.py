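"""Discrete swimmer model: geometry, elasticity and preferred-curvature drive.

A swimmer is a chain of ``N_flag`` spherical flagellum segments of radius
``b`` at spacing ``ds = l/N_flag``, attached to an oblate-spheroid head.
Body 0 is the head; bodies ``1..N_flag`` are segments.  Each body carries a
position and an orientation; for the planar dynamics studied here the
orientation is a rotation about the out-of-plane axis ``z`` and the segment
tangent is ``t = (cos th, sin th, 0)``.

Inextensibility and connectivity are imposed through joint constraints

    g_j = Y_{j+1} - Y_j - (ds/2) (t_j + t_{j+1}) = 0      (j = 1..N_flag-1)

together with the head linkage (attachment-point coincidence)

    g_0 = Y_1 - (ds/2) t_1 - Y_head - 1.1 a e_h = 0

and a clamped-end condition ``t_1 parallel to e_h``.  Each constraint has a
Lagrange multiplier; the associated forces and torques are the exact
negative gradients of ``Lambda . g`` with respect to positions and
rotations, so the constraint system does no work and exerts zero net force
and torque on the swimmer.

The flagellum is driven toward a preferred curvature wave

    kappa_0(s, t) = K0 A(s) sin(k s + Phi + phi),      dPhi/dt = -omega,

with a linear amplitude ramp A(s) from 1 to 0 over the final ``gamma_tip``
fraction of the flagellum, mimicking the decaying waveform amplitude
observed near the tip of real sperm flagella.  The drive enters as joint
torques proportional to the deviation of the discrete curvature from
``kappa_0``; all actuation is internal (torque pairs), so the swimmer is
force- and torque-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import PhysicalParams

__all__ = [
    "SwimmerState", "FlagellumState", "ForceBundle",
    "preferred_curvature", "ramp_amplitude",
    "bending_torques", "driving_torques",
    "constraint_residuals", "constraint_forces",
    "driven_elastic_energy", "assemble_swimmer_forces",
    "straight_swimmer", "joint_arclengths",
]

Z_HAT = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# state containers


@dataclass
class SwimmerState:
    """Configuration of one swimmer.

    ``pos`` has shape (N_flag + 1, 3) with the head first, ``theta`` the
    in-plane orientation angle of each body (the head angle is the direction
    of the head axis ``e_h``, pointing from the head toward the flagellum).
    ``phi`` is the swimmer's static phase offset, ``Phi`` the integrated
    drive phase and ``omega_cur`` the current undulation frequency.
    """

    pos: np.ndarray
    theta: np.ndarray
    phi: float = 0.0
    Phi: float = 0.0
    omega_cur: float = 0.0

    @property
    def n_flag(self) -> int:
        return self.pos.shape[0] - 1

    @property
    def head_pos(self) -> np.ndarray:
        return self.pos[0]

    @property
    def Y(self) -> np.ndarray:
        """Segment positions, shape (N_flag, 3)."""
        return self.pos[1:]

    @property
    def t_hat(self) -> np.ndarray:
        """Unit tangent of every body (head axis first), shape (B, 3)."""
        t = np.zeros_like(self.pos)
        t[:, 0] = np.cos(self.theta)
        t[:, 1] = np.sin(self.theta)
        return t

    @property
    def quaternions(self) -> np.ndarray:
        """Unit quaternions (w, x, y, z) for rotations about z by theta."""
        q = np.zeros(self.pos.shape[:-1] + (4,))
        q[..., 0] = np.cos(0.5 * self.theta)
        q[..., 3] = np.sin(0.5 * self.theta)
        return q

    @property
    def head_q(self) -> np.ndarray:
        return self.quaternions[0]

    def flagellum(self, params: PhysicalParams) -> "FlagellumState":
        return FlagellumState(
            N_flag=self.n_flag, ds=params.l / self.n_flag,
            Y=self.Y.copy(), q=self.quaternions[1:],
            t_hat=self.t_hat[1:],
        )

    def copy(self) -> "SwimmerState":
        return replace(self, pos=self.pos.copy(), theta=self.theta.copy())


@dataclass
class FlagellumState:
    """Read-only view of the flagellum part of a swimmer state."""

    N_flag: int
    ds: float
    Y: np.ndarray
    q: np.ndarray
    t_hat: np.ndarray


@dataclass
class ForceBundle:
    """Per-body forces/torques split by physical origin.

    Shapes are (B, 3) with the head first.  ``Lambda`` holds the joint
    multipliers (N_flag, 3) and ``mu`` the clamp multiplier (scalar torque
    about z in the planar setting).
    """

    F_C: np.ndarray
    T_C: np.ndarray
    T_B: np.ndarray
    T_D: np.ndarray
    F_steric: np.ndarray
    Lambda: np.ndarray
    mu: float

    @property
    def total_force(self) -> np.ndarray:
        return self.F_C + self.F_steric

    @property
    def total_torque(self) -> np.ndarray:
        return self.T_C + self.T_B + self.T_D


# ---------------------------------------------------------------------------
# actuation


def ramp_amplitude(s, params: PhysicalParams):
    """Tip ramp A(s): 1 on the proximal part, linear to 0 at s = l."""
    s = np.asarray(s, dtype=float)
    l, g = params.l, params.gamma_tip
    return np.clip((l - s) / (g * l), 0.0, 1.0)


def preferred_curvature(s, phi: float, Phi: float, params: PhysicalParams):
    """Preferred curvature kappa_0(s) = K0 A(s) sin(k s + Phi + phi).

    ``s`` may be scalar or array, and must lie in [0, l].
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < -1e-12) or np.any(s > params.l * (1 + 1e-12)):
        raise ValueError("arclength outside [0, l]")
    return params.K0 * ramp_amplitude(s, params) * np.sin(
        params.k_wave * s + Phi + phi)


def joint_arclengths(n_flag: int, params: PhysicalParams) -> np.ndarray:
    """Arclengths of the interior joints, s_j = j ds for j = 1..N_flag-1."""
    ds = params.l / n_flag
    return ds * np.arange(1, n_flag)


# ---------------------------------------------------------------------------
# torques

def _pair_torques(n_bodies: int, joint_torque_z: np.ndarray) -> np.ndarray:
    """Distribute joint torques tau_j z as +tau on segment j, -tau on j+1.

    ``joint_torque_z`` has one entry per interior joint (between segments
    j and j+1, j = 1..N_flag-1); returns per-body torques, head included.
    """
    T = np.zeros((n_bodies, 3))
    T[1:-1, 2] += joint_torque_z
    T[2:, 2] -= joint_torque_z
    return T


def _discrete_curvature(state: SwimmerState, ds: float) -> np.ndarray:
    """Signed discrete curvature at interior joints, sin(dtheta)/ds."""
    t = state.t_hat[1:]
    cross_z = t[:-1, 0] * t[1:, 1] - t[:-1, 1] * t[1:, 0]
    return cross_z / ds


def bending_torques(state: SwimmerState, params: PhysicalParams) -> np.ndarray:
    """Elastic bending torques, (K_B/ds) t_j x t_{j+1} pairs at each joint."""
    ds = params.l / state.n_flag
    kappa = _discrete_curvature(state, ds)
    return _pair_torques(state.pos.shape[0], params.K_B * kappa)


def driving_torques(state: SwimmerState, params: PhysicalParams) -> np.ndarray:
    """Driven elastic torques: bending measured against the preferred shape.

    Joint torque pairs +/- K_B (kappa_disc - kappa_0(s_j)) z.  The pure
    actuation part (ForceBundle.T_D) is this minus ``bending_torques``.
    Summed over the swimmer the torques cancel exactly: actuation is
    internal.
    """
    ds = params.l / state.n_flag
    kappa = _discrete_curvature(state, ds)
    kappa0 = preferred_curvature(joint_arclengths(state.n_flag, params),
                                 state.phi, state.Phi, params)
    return _pair_torques(state.pos.shape[0], params.K_B * (kappa - kappa0))


def driven_elastic_energy(state: SwimmerState, params: PhysicalParams) -> float:
    """Discrete driven elastic energy whose negative gradient is the torques.

    E = sum_j [ (K_B/ds)(1 - t_j . t_{j+1}) - K_B kappa_0(s_j) dtheta_j ].
    """
    ds = params.l / state.n_flag
    t = state.t_hat[1:]
    dots = np.einsum("ij,ij->i", t[:-1], t[1:])
    dth = np.diff(np.unwrap(state.theta[1:]))
    kappa0 = preferred_curvature(joint_arclengths(state.n_flag, params),
                                 state.phi, state.Phi, params)
    return float(np.sum(params.K_B / ds * (1.0 - dots)
                        - params.K_B * kappa0 * dth))


# ---------------------------------------------------------------------------
# constraints


def constraint_residuals(state: SwimmerState,
                         params: PhysicalParams) -> tuple[np.ndarray, np.ndarray]:
    """Joint residuals (N_flag, 3) and the clamp residual (3,).

    Row 0 is the head linkage g_0 = Y_1 - (ds/2) t_1 - Y_h - 1.1 a e_h;
    rows j >= 1 are the segment joints
    g_j = Y_{j+1} - Y_j - (ds/2)(t_j + t_{j+1}).  The clamp residual is
    t_1 - e_h.  All zero iff the configuration is admissible.
    """
    ds = params.l / state.n_flag
    t = state.t_hat
    g = np.empty((state.n_flag, 3))
    g[0] = state.pos[1] - 0.5 * ds * t[1] - state.pos[0] \
        - params.head_offset * t[0]
    g[1:] = state.pos[2:] - state.pos[1:-1] - 0.5 * ds * (t[1:-1] + t[2:])
    clamp = t[1] - t[0]
    return g, clamp


def constraint_forces(state: SwimmerState, Lambda: np.ndarray,
                      mu: float, params: PhysicalParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Forces/torques conjugate to the constraints, -d(Lambda . g)/dx.

    ``Lambda`` has one 3-vector per joint (head linkage first), ``mu`` is
    the clamp multiplier (torque about z).  Body n receives the force
    Lambda_n - Lambda_{n-1} (boundary multipliers zero), so the total
    vanishes; torques follow from virtual work on rotations and balance the
    force moments exactly on the constraint manifold.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    if Lambda.shape != (state.n_flag, 3):
        raise ValueError("need one multiplier 3-vector per joint")
    B = state.pos.shape[0]
    ds = params.l / state.n_flag
    t = state.t_hat

    F = np.zeros((B, 3))
    F[0] = Lambda[0]
    F[1:-1] = Lambda[1:] - Lambda[:-1]
    F[-1] = -Lambda[-1]

    T = np.zeros((B, 3))
    # head: offset arm 1.1a e_h from linkage, plus clamp reaction +mu z
    T[0] = params.head_offset * np.cross(t[0], Lambda[0])
    T[0, 2] += mu
    # segment j: (ds/2) t_j x (Lambda_j + Lambda_{j-1}); the boundary
    # multiplier beyond the tip is zero, so the last segment sees only
    # its upstream joint
    arm = np.zeros((state.n_flag, 3))
    arm[:-1] = Lambda[1:] + Lambda[:-1]
    arm[-1] = Lambda[-1]
    T[1:] += 0.5 * ds * np.cross(t[1:], arm)
    T[1, 2] -= mu
    return F, T


def assemble_swimmer_forces(state: SwimmerState, Lambda: np.ndarray,
                            mu: float, params: PhysicalParams) -> ForceBundle:
    """All non-hydrodynamic forces/torques of a single swimmer."""
    F_C, T_C = constraint_forces(state, Lambda, mu, params)
    T_B = bending_torques(state, params)
    T_full = driving_torques(state, params)
    return ForceBundle(F_C=F_C, T_C=T_C, T_B=T_B, T_D=T_full - T_B,
                       F_steric=np.zeros_like(F_C),
                       Lambda=np.asarray(Lambda, dtype=float), mu=mu)


# ---------------------------------------------------------------------------
# vectorized planar assembly (hot path used by the integrator)


def planar_internal_forces(x: np.ndarray, th: np.ndarray, Lam: np.ndarray,
                           mu: np.ndarray, phase: np.ndarray,
                           params: PhysicalParams):
    """Internal forces for S swimmers at once, planar coordinates.

    Parameters
    ----------
    x : (S, B, 2) body positions (head first), th : (S, B) angles,
    Lam : (S, N_flag, 2) joint multipliers, mu : (S,) clamp multipliers,
    phase : (S,) current drive phase Phi + phi per swimmer.

    Returns
    -------
    F : (S, B, 2), Tz : (S, B), g : (S, N_flag, 2), h : (S,)
        Constraint-plus-drive forces and torques, and the constraint
        residuals (joint gaps and clamp angle mismatch).

    Identical physics to the single-swimmer 3-vector API above; the two are
    cross-checked in the test suite.
    """
    S, B = th.shape
    n_flag = B - 1
    ds = params.l / n_flag
    c, s = np.cos(th), np.sin(th)
    t = np.stack([c, s], axis=-1)                       # (S, B, 2)

    # driven elastic joint torques
    cross = c[:, 1:-1] * s[:, 2:] - s[:, 1:-1] * c[:, 2:]
    kappa = cross / ds
    s_j = ds * np.arange(1, n_flag)
    amp = np.clip((params.l - s_j) / (params.gamma_tip * params.l), 0.0, 1.0)
    kappa0 = params.K0 * amp[None, :] * np.sin(
        params.k_wave * s_j[None, :] + phase[:, None])
    tau = params.K_B * (kappa - kappa0)                 # (S, n_flag-1)

    Tz = np.zeros((S, B))
    Tz[:, 1:-1] += tau
    Tz[:, 2:] -= tau

    # constraint residuals
    g = np.empty((S, n_flag, 2))
    g[:, 0] = x[:, 1] - 0.5 * ds * t[:, 1] - x[:, 0] \
        - params.head_offset * t[:, 0]
    g[:, 1:] = x[:, 2:] - x[:, 1:-1] - 0.5 * ds * (t[:, 1:-1] + t[:, 2:])
    h = th[:, 1] - th[:, 0]

    # constraint forces and torques
    F = np.empty((S, B, 2))
    F[:, 0] = Lam[:, 0]
    F[:, 1:-1] = Lam[:, 1:] - Lam[:, :-1]
    F[:, -1] = -Lam[:, -1]

    arm = np.empty((S, n_flag, 2))
    arm[:, :-1] = Lam[:, 1:] + Lam[:, :-1]
    arm[:, -1] = Lam[:, -1]
    tl = t[:, 1:]
    Tz[:, 1:] += 0.5 * ds * (tl[..., 0] * arm[..., 1] - tl[..., 1] * arm[..., 0])
    Tz[:, 0] += params.head_offset * (
        t[:, 0, 0] * Lam[:, 0, 1] - t[:, 0, 1] * Lam[:, 0, 0]) + mu
    Tz[:, 1] -= mu
    return F, Tz, g, h


# ---------------------------------------------------------------------------
# construction


def straight_swimmer(params: PhysicalParams, n_flag: int = 29, *,
                     head_pos=(0.0, 0.0, 0.0), theta: float = 0.0,
                     phi: float = 0.0, Phi: float = 0.0) -> SwimmerState:
    """An admissible straight swimmer pointing along angle ``theta``.

    The head axis points from the head toward the flagellum, so the swimmer
    will swim in the ``-t`` direction (opposite the tangent) once driven.
    """
    ds = params.l / n_flag
    e = np.array([np.cos(theta), np.sin(theta), 0.0])
    pos = np.zeros((n_flag + 1, 3))
    pos[0] = np.asarray(head_pos, dtype=float)
    pos[1] = pos[0] + (params.head_offset + 0.5 * ds) * e
    for j in range(2, n_flag + 1):
        pos[j] = pos[j - 1] + ds * e
    th = np.full(n_flag + 1, float(theta))
    return SwimmerState(pos=pos, theta=th, phi=phi, Phi=Phi,
                        omega_cur=params.omega_bar)
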
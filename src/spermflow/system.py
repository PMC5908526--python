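"""Planar multi-swimmer system state and force assembly.

Swimmer motion is restricted to the film midplane, so the dynamical state
is planar: per body an in-plane position and an orientation angle about
the film normal, plus per-joint Lagrange multipliers.  Out-of-plane
coordinates are structural constants (z = L_z/2, no tilt), which realizes
the midplane restriction exactly: U_z = 0 and W_x = W_y = 0 by
construction, and the projection's reaction is never added to the fluid.

Bodies are ordered head-first within each swimmer; flattened body index
p = s * (N_flag + 1) + b.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import GridSpec, PhysicalParams
from .swimmer import SwimmerState, planar_internal_forces, straight_swimmer

__all__ = ["PlanarSystem", "steric_force_pairs", "steric_pair_list"]


@dataclass
class PlanarSystem:
    """State of S swimmers with B = N_flag + 1 bodies each."""

    params: PhysicalParams
    grid: GridSpec
    x: np.ndarray            # (S, B, 2) body positions, head first
    th: np.ndarray           # (S, B) orientation angles
    phi: np.ndarray          # (S,) static phase offsets
    Phi: np.ndarray          # (S,) integrated drive phase
    omega: np.ndarray        # (S,) current undulation frequency
    Lam: np.ndarray          # (S, N_flag, 2) joint multipliers
    mu: np.ndarray           # (S,) clamp multipliers
    t: float = 0.0
    nstep: int = 0

    @property
    def S(self) -> int:
        return self.x.shape[0]

    @property
    def B(self) -> int:
        return self.x.shape[1]

    @property
    def n_flag(self) -> int:
        return self.B - 1

    @property
    def ds(self) -> float:
        return self.params.l / self.n_flag

    @property
    def kinds(self) -> np.ndarray:
        """Body kinds, head = 1, segments = 0, flattened over swimmers."""
        k = np.zeros(self.B, dtype=np.int64)
        k[0] = 1
        return np.tile(k, self.S)

    @property
    def steric_radii(self) -> np.ndarray:
        r = np.full(self.B, self.params.b)
        r[0] = self.params.a
        return np.tile(r, self.S)

    def positions_flat(self) -> np.ndarray:
        return self.x.reshape(-1, 2)

    def com(self) -> np.ndarray:
        """Per-swimmer centre of mass (uniform body weights), (S, 2)."""
        return self.x.mean(axis=1)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions_flat(), self.grid.L)

    def swimmer_state(self, s: int) -> SwimmerState:
        pos = np.zeros((self.B, 3))
        pos[:, :2] = self.x[s]
        pos[:, 2] = self.grid.midplane_z
        return SwimmerState(pos=pos, theta=self.th[s].copy(),
                            phi=float(self.phi[s]), Phi=float(self.Phi[s]),
                            omega_cur=float(self.omega[s]))

    def copy(self) -> "PlanarSystem":
        return replace(
            self, x=self.x.copy(), th=self.th.copy(), phi=self.phi.copy(),
            Phi=self.Phi.copy(), omega=self.omega.copy(),
            Lam=self.Lam.copy(), mu=self.mu.copy())

    @classmethod
    def from_swimmers(cls, swimmers, params: PhysicalParams,
                      grid: GridSpec) -> "PlanarSystem":
        """Build a system from a list of (planar) SwimmerState objects."""
        S = len(swimmers)
        B = swimmers[0].pos.shape[0]
        nf = B - 1
        x = np.stack([sw.pos[:, :2] for sw in swimmers])
        th = np.stack([sw.theta for sw in swimmers])
        return cls(
            params=params, grid=grid, x=x, th=th,
            phi=np.array([sw.phi for sw in swimmers], dtype=float),
            Phi=np.array([sw.Phi for sw in swimmers], dtype=float),
            omega=np.array([sw.omega_cur for sw in swimmers], dtype=float),
            Lam=np.zeros((S, nf, 2)), mu=np.zeros(S),
        )

    @classmethod
    def solitary(cls, params: PhysicalParams, grid: GridSpec, *,
                 n_flag: int = 29, theta: float = 0.0,
                 center=None) -> "PlanarSystem":
        """One swimmer, straight, centred in the box unless told otherwise."""
        sw = straight_swimmer(params, n_flag, theta=theta)
        sys_ = cls.from_swimmers([sw], params, grid)
        target = np.asarray(center if center is not None
                            else (grid.L / 2, grid.L / 2), dtype=float)
        sys_.x += target - sys_.x.mean(axis=(0, 1))
        return sys_


# ---------------------------------------------------------------------------
# steric repulsion


def steric_pair_list(system: PlanarSystem, *, chi: float = 1.1,
                     skin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Candidate steric pairs (i, j) within chi (a_i + a_j) + skin.

    Uses a periodic KD-tree in the plane; bonded neighbours (adjacent
    bodies of the same swimmer, including the head linkage) are excluded.
    The ``skin`` margin lets one list be reused for all quasi-Newton
    iterations of a step.
    """
    from scipy.spatial import cKDTree

    pos = system.wrapped_positions()
    radii = system.steric_radii
    rmax = chi * 2 * np.max(radii) + skin
    tree = cKDTree(pos, boxsize=system.grid.L)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    i, j = pairs[:, 0], pairs[:, 1]
    cut = chi * (radii[i] + radii[j]) + skin
    d = pos[i] - pos[j]
    L = system.grid.L
    d -= L * np.round(d / L)
    keep = np.einsum("ij,ij->i", d, d) < cut ** 2
    i, j = i[keep], j[keep]
    same = (i // system.B) == (j // system.B)
    bonded = same & (np.abs(i - j) == 1)
    keep = ~bonded
    return i[keep], j[keep]


def steric_force_pairs(pos_flat: np.ndarray, i: np.ndarray, j: np.ndarray,
                       radii: np.ndarray, *, F_S: float, L: float,
                       chi: float = 1.1) -> np.ndarray:
    """Pairwise quartic barrier forces on the flattened body set.

    The magnitude is F_S [(R^2 - r^2)/(R^2 - r_c^2)]^4 along the centre
    line for r < R = chi (a_i + a_j), zero outside, and exactly F_S at
    contact r = r_c = a_i + a_j.  Forces come in equal and opposite pairs
    (Newton's third law holds to round-off).  Near-coincident centres are
    clamped with a warning.
    """
    F = np.zeros_like(pos_flat)
    if i.size == 0:
        return F
    d = pos_flat[i] - pos_flat[j]
    d -= L * np.round(d / L)
    r2 = np.einsum("ij,ij->i", d, d)
    rc = radii[i] + radii[j]
    R = chi * rc
    tiny = r2 < (0.05 * rc) ** 2
    if np.any(tiny):
        import warnings
        warnings.warn("steric clamp: nearly coincident body centres")
        r2 = np.maximum(r2, (0.05 * rc) ** 2)
    act = r2 < R * R
    if not np.any(act):
        return F
    ii, jj = i[act], j[act]
    dd, rr2 = d[act], r2[act]
    Ra, rca = R[act], rc[act]
    mag = F_S * ((Ra ** 2 - rr2) / (Ra ** 2 - rca ** 2)) ** 4
    fvec = (mag / np.sqrt(rr2))[:, None] * dd
    np.add.at(F, ii, fvec)
    np.add.at(F, jj, -fvec)
    return F


# ---------------------------------------------------------------------------
# total force assembly


def system_forces(x: np.ndarray, th: np.ndarray, Lam: np.ndarray,
                  mu: np.ndarray, phase: np.ndarray,
                  system: PlanarSystem, steric_pairs=None):
    """All non-hydrodynamic forces at a trial configuration.

    Returns F (S, B, 2), Tz (S, B), constraint residuals g (S, Nf, 2) and
    clamp residuals h (S,).  ``steric_pairs`` is a precomputed (i, j)
    candidate list; omit for no steric interactions (single swimmer).
    """
    F, Tz, g, h = planar_internal_forces(x, th, Lam, mu, phase,
                                         system.params)
    if steric_pairs is not None and steric_pairs[0].size:
        Fs = steric_force_pairs(
            x.reshape(-1, 2), steric_pairs[0], steric_pairs[1],
            system.steric_radii, F_S=system.params.F_S, L=system.grid.L)
        F += Fs.reshape(F.shape)
    return F, Tz, g, h
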
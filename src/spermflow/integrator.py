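"""Implicit time integration: BDF2 with a quasi-Newton (Broyden) solver.

Each step solves the fully coupled nonlinear system for the new body
positions, orientations and Lagrange multipliers: the kinematic equations

    X_new - (4 X_n - X_{n-1})/3 - (2 dt / 3) V(X_new, Lambda_new) = 0

(backward Euler on the first step to build the history), stacked with the
connectivity and clamp constraint residuals.  V is the mobility solve
applied to all forces at the trial state, so elasticity, actuation,
steric barriers and hydrodynamics are treated implicitly — required by the
stiffness of the bending term at the working time step (T/300).

The unknown vector is scaled so the residual Jacobian is O(1): lengths by
the segment spacing ds, multipliers by the force that moves a segment one
ds per step.  Broyden's "bad" (inverse-Jacobian secant) update is used in
limited-memory form with a restart cap; the initial inverse Jacobian is
either an identity scaling or, in production stepping, a block-diagonal
finite-difference Jacobian per swimmer refreshed adaptively, which cuts
the iteration count substantially for stiff filaments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .params import SolverSettings
from .system import PlanarSystem, steric_pair_list, system_forces

__all__ = ["broyden_solve", "BroydenResult", "Stepper", "StepDiagnostics",
           "StepFailure"]


class StepFailure(RuntimeError):
    """The nonlinear solve did not converge; carries the offending state."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics


@dataclass
class BroydenResult:
    x: np.ndarray
    iterations: int
    residual_norm: float
    converged: bool


def broyden_solve(residual_fn, x0, settings: SolverSettings, *,
                  apply_B0=None, restart_every: int = 50,
                  max_backtracks: int = 4, memory=None) -> BroydenResult:
    """Solve residual_fn(x) = 0 by limited-memory 'bad' Broyden iteration.

    The inverse-Jacobian approximation starts from ``apply_B0`` (identity
    scaling when omitted) and accumulates rank-one secant corrections
    B <- B + ((s - B y) / y.y) y^T, discarded every ``restart_every``
    iterations.  A short backtracking line search guards against steps
    that increase the residual norm.  Convergence is declared at
    ||R|| <= broyden_tol * sqrt(n).
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    tol = settings.broyden_tol * np.sqrt(n)
    if apply_B0 is None:
        apply_B0 = lambda v: v

    if memory is None:
        us: list[np.ndarray] = []
        ys: list[np.ndarray] = []
    else:
        us, ys = memory

    def apply_B(v):
        w = apply_B0(v)
        for u, y in zip(us, ys):
            w = w + u * (y @ v)
        return w

    R = np.asarray(residual_fn(x), dtype=float)
    norm = norm0 = np.linalg.norm(R)
    if norm <= tol:
        return BroydenResult(x, 0, norm, True)

    for it in range(1, settings.broyden_maxit + 1):
        dx = -apply_B(R)
        step = 1.0
        best = None
        for _ in range(max_backtracks + 1):
            x_new = x + step * dx
            R_new = np.asarray(residual_fn(x_new), dtype=float)
            norm_new = np.linalg.norm(R_new)
            if np.isfinite(norm_new) and (best is None or norm_new < best[2]):
                best = (x_new, R_new, norm_new)
            # Broyden iterations are legitimately non-monotone; only guard
            # against blow-ups
            if np.isfinite(norm_new) and norm_new < 2.0 * norm:
                break
            step *= 0.25
        else:
            if best is None:        # nothing finite: bail out with tiny step
                x_new = x + 1e-8 * dx
                R_new = np.asarray(residual_fn(x_new), dtype=float)
                norm_new = np.linalg.norm(R_new)
            else:
                x_new, R_new, norm_new = best
        s = x_new - x
        y = R_new - R
        yy = y @ y
        if yy > 0.0:
            if len(us) >= restart_every:
                us.clear()
                ys.clear()
            us.append((s - apply_B(y)) / yy)
            ys.append(y)
        x, R, norm = x_new, R_new, norm_new
        if norm <= tol:
            return BroydenResult(x, it, norm, True)
        if not np.isfinite(norm) or norm > 1e5 * max(norm0, tol):
            # diverging (e.g. a steric jam the Jacobian cannot capture):
            # fail fast so the caller can rebuild and retry
            return BroydenResult(x, it, norm, False)
    return BroydenResult(x, settings.broyden_maxit, norm, False)


# ---------------------------------------------------------------------------
# DOF packing


class _DofMap:
    """Flatten (x, th, Lam, mu) <-> scaled unknown vector, per swimmer."""

    def __init__(self, system: PlanarSystem, dt: float):
        p = system.params
        self.S, self.B = system.S, system.B
        self.nf = system.n_flag
        ds = system.ds
        c = 2.0 * dt / 3.0
        m0 = 1.0 / (6.0 * np.pi * p.eta * p.b)
        mrot = 1.0 / (8.0 * np.pi * p.eta * p.b ** 3)
        self.L_ref = ds
        self.F_ref = ds / (c * m0)
        self.mu_ref = 1.0 / (c * mrot)
        self.n_per = 3 * self.B + 2 * self.nf + 1
        self.n = self.S * self.n_per

    def pack(self, x, th, Lam, mu):
        S, B, nf = self.S, self.B, self.nf
        out = np.empty((S, self.n_per))
        out[:, :2 * B] = (x / self.L_ref).reshape(S, -1)
        out[:, 2 * B:3 * B] = th
        out[:, 3 * B:3 * B + 2 * nf] = (Lam / self.F_ref).reshape(S, -1)
        out[:, -1] = mu / self.mu_ref
        return out.ravel()

    def unpack(self, vec):
        S, B, nf = self.S, self.B, self.nf
        v = vec.reshape(S, self.n_per)
        x = v[:, :2 * B].reshape(S, B, 2) * self.L_ref
        th = v[:, 2 * B:3 * B].copy()
        Lam = v[:, 3 * B:3 * B + 2 * nf].reshape(S, nf, 2) * self.F_ref
        mu = v[:, -1] * self.mu_ref
        return x, th, Lam, mu

    def pack_residual(self, r_x, r_th, g, h):
        S, B, nf = self.S, self.B, self.nf
        out = np.empty((S, self.n_per))
        out[:, :2 * B] = (r_x / self.L_ref).reshape(S, -1)
        out[:, 2 * B:3 * B] = r_th
        out[:, 3 * B:3 * B + 2 * nf] = (g / self.L_ref).reshape(S, -1)
        out[:, -1] = h
        return out.ravel()


@dataclass
class StepDiagnostics:
    """Per-step solver and force information handed to observers."""

    iterations: int
    residual_norm: float
    constraint_max: float
    U: np.ndarray            # (S, B, 2) body velocities
    Wz: np.ndarray           # (S, B) angular velocities
    F_fluid: np.ndarray      # (S, B, 2) forces exerted on the fluid
    Tz_fluid: np.ndarray     # (S, B) torques exerted on the fluid


class Stepper:
    """Advances a PlanarSystem in time.

    ``backend`` provides ``velocities(pos, theta, kinds, F, Tz)``; steric
    interactions are enabled automatically for multi-swimmer systems.  The
    first step is backward Euler to bootstrap the two-step BDF2 history.
    A finite-difference inverse-Jacobian seed (full for small
    multi-swimmer systems, per-swimmer block-diagonal otherwise) is built
    on the first step and refreshed whenever convergence degrades.
    """

    def __init__(self, system: PlanarSystem, settings: SolverSettings,
                 backend, *, use_steric: bool | None = None,
                 use_fd_jacobian: bool = True,
                 refresh_iters: int = 60, skin_factor: float = 0.5):
        self.system = system
        self.settings = settings
        self.backend = backend
        self.use_steric = (system.S > 1) if use_steric is None else use_steric
        self.use_fd_jacobian = use_fd_jacobian
        self.refresh_iters = refresh_iters
        self.skin = skin_factor * system.params.b
        self.dof = _DofMap(system, settings.dt)
        self._prev: tuple[np.ndarray, np.ndarray] | None = None  # (x, th) one step back
        self._lu = None
        self._lu_full = False
        self.full_jacobian_max = 2600   # dof cap for the full FD Jacobian
        self._memory: tuple[list, list] = ([], [])  # secant pairs carried across steps
        self.total_iterations = 0

    # -- residual ---------------------------------------------------------

    def _make_residual(self, x_star, th_star, c, phase, pairs):
        sys_ = self.system
        dof = self.dof
        kinds = sys_.kinds

        def residual(vec):
            x, th, Lam, mu = dof.unpack(vec)
            F, Tz, g, h = system_forces(x, th, Lam, mu, phase, sys_, pairs)
            U, Wz = self.backend.velocities(
                x.reshape(-1, 2), th.ravel(), kinds,
                F.reshape(-1, 2), Tz.ravel())
            r_x = x - x_star - c * U.reshape(x.shape)
            r_th = th - th_star - c * Wz.reshape(th.shape)
            return dof.pack_residual(r_x, r_th, g, h)

        return residual

    # -- block-diagonal FD Jacobian ---------------------------------------

    def _build_fd_jacobian(self, residual, vec0, R0):
        """Finite-difference inverse-Jacobian seed.

        For a single swimmer (or large suspensions) a block-diagonal
        Jacobian is built by perturbing the same local degree of freedom
        of every swimmer at once (n_per + 1 residual calls).  Small
        multi-swimmer systems instead build the full Jacobian, which
        captures the steric and hydrodynamic cross-swimmer coupling that
        dominates during collisions.
        """
        n_per, S = self.dof.n_per, self.dof.S
        eps = 1e-6
        if S > 1 and S * n_per <= self.full_jacobian_max:
            n = S * n_per
            J = np.empty((n, n))
            for i in range(n):
                pert = vec0.copy()
                pert[i] += eps
                J[:, i] = (residual(pert) - R0) / eps
            self._lu = [lu_factor(J)]
            self._lu_full = True
            return
        J = np.zeros((S, n_per, n_per))
        for i in range(n_per):
            pert = vec0.copy().reshape(S, n_per)
            pert[:, i] += eps
            dR = (residual(pert.ravel()) - R0).reshape(S, n_per)
            J[:, :, i] = dR / eps
        self._lu = [lu_factor(J[s]) for s in range(S)]
        self._lu_full = False

    def _apply_B0(self, v):
        if self._lu is None:
            return v
        if self._lu_full:
            return lu_solve(self._lu[0], v)
        out = np.empty_like(v)
        n_per = self.dof.n_per
        vv = v.reshape(self.dof.S, n_per)
        for s, lu in enumerate(self._lu):
            out.reshape(self.dof.S, n_per)[s] = lu_solve(lu, vv[s])
        return out

    # -- stepping ----------------------------------------------------------

    def step(self) -> StepDiagnostics:
        sys_ = self.system
        dt = self.settings.dt
        dof = self.dof

        Phi_new = sys_.Phi - sys_.omega * dt
        phase = Phi_new + sys_.phi

        pairs = steric_pair_list(sys_, skin=self.skin) \
            if self.use_steric else None

        if self._prev is None:
            # backward Euler bootstrap for the two-step history
            c = dt
            x_star, th_star = sys_.x, sys_.th
            x_g, th_g = sys_.x, sys_.th
        else:
            c = 2.0 * dt / 3.0
            x0, t0 = self._prev
            x_star = (4.0 * sys_.x - x0) / 3.0
            th_star = (4.0 * sys_.th - t0) / 3.0
            # warm start: linear extrapolation of the configuration
            x_g, th_g = 2.0 * sys_.x - x0, 2.0 * sys_.th - t0

        residual = self._make_residual(x_star, th_star, c, phase, pairs)
        guess = dof.pack(x_g, th_g, sys_.Lam, sys_.mu)

        if self.use_fd_jacobian and self._lu is None:
            self._build_fd_jacobian(residual, guess, residual(guess))

        res = broyden_solve(residual, guess, self.settings,
                            apply_B0=self._apply_B0, memory=self._memory)
        if (not res.converged) and self.use_fd_jacobian:
            # stale Jacobian: rebuild once and retry
            self._memory = ([], [])
            self._build_fd_jacobian(residual, guess, residual(guess))
            res = broyden_solve(residual, guess, self.settings,
                                apply_B0=self._apply_B0, memory=self._memory)
        if not res.converged:
            raise StepFailure(
                f"Broyden failed at t={sys_.t:.4f}: |R|={res.residual_norm:.3e}")
        if self.use_fd_jacobian and res.iterations > self.refresh_iters:
            self._lu = None     # refresh on the next step
            self._memory = ([], [])

        x, th, Lam, mu = dof.unpack(res.x)
        F, Tz, g, h = system_forces(x, th, Lam, mu, phase, sys_, pairs)
        U, Wz = self.backend.velocities(
            x.reshape(-1, 2), th.ravel(), sys_.kinds,
            F.reshape(-1, 2), Tz.ravel())
        cmax = float(max(np.max(np.abs(g)), np.max(np.abs(h))))
        ctol = self.settings.constraint_tol_factor * sys_.ds
        if cmax > 100.0 * ctol:
            raise StepFailure(
                f"constraints drifted: max residual {cmax:.3e} at t={sys_.t:.4f}")

        self._prev = (sys_.x.copy(), sys_.th.copy())
        sys_.x, sys_.th = x, th
        sys_.Lam, sys_.mu = Lam, mu
        sys_.Phi = Phi_new
        sys_.t += dt
        sys_.nstep += 1
        self.total_iterations += res.iterations
        return StepDiagnostics(
            iterations=res.iterations, residual_norm=res.residual_norm,
            constraint_max=cmax,
            U=U.reshape(sys_.x.shape), Wz=Wz.reshape(sys_.th.shape),
            F_fluid=F, Tz_fluid=Tz)

    def run(self, n_steps: int, observers=()) -> None:
        for _ in range(n_steps):
            diag = self.step()
            for obs in observers:
                obs(self.system, diag)
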
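"""Multi-swimmer orchestration: initial conditions, frequency noise, runs.

Swimmers are placed in the periodic film in one of four modes: ``polar``
(uniform placement, all aligned to swim in -x, random phases), an
``isotropic`` variant with random orientations, a phase-shifted parallel
``pair``, or a ``solitary`` swimmer.  Per-swimmer undulation frequencies
may be redrawn from a lognormal law every mean period T, which models the
cell-to-cell and temporal variability of real sperm samples; its strength
sigma_omega controls whether the suspension synchronizes into clusters
(sigma_omega = 0) or reaches a turbulence-like state (sigma_omega =
omega/5).  The drive phase integrates continuously through redraws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrator import Stepper
from .params import GridSpec, PhysicalParams, SolverSettings, SuspensionConfig
from .swimmer import straight_swimmer
from .system import PlanarSystem

__all__ = ["FrequencyProcess", "sample_frequencies", "initialize", "run"]


# ---------------------------------------------------------------------------
# stochastic frequency modulation


def sample_frequencies(omega_bar: float, sigma_omega: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw per-swimmer frequencies from a lognormal law.

    Parameterized by the linear-scale mean and standard deviation:
    mu = ln(om^2 / sqrt(om^2 + s^2)), s_log^2 = ln(1 + s^2/om^2), so the
    sample mean and sd converge to omega_bar and sigma_omega.  All draws
    are positive; sigma_omega = 0 returns omega_bar exactly.
    """
    if omega_bar <= 0 or sigma_omega < 0:
        raise ValueError("need omega_bar > 0 and sigma_omega >= 0")
    if sigma_omega == 0.0:
        return np.full(n, omega_bar)
    ratio2 = (sigma_omega / omega_bar) ** 2
    mu = np.log(omega_bar / np.sqrt(1.0 + ratio2))
    s = np.sqrt(np.log(1.0 + ratio2))
    return rng.lognormal(mean=mu, sigma=s, size=n)


@dataclass
class FrequencyProcess:
    """Synchronous lognormal redraws of the undulation frequency.

    Frequencies are redrawn for every swimmer at multiples of the mean
    period T; the integrated phase Phi is continuous across redraws
    because only d Phi / dt changes.
    """

    omega_bar: float
    sigma_omega: float
    redraw_interval: float
    rng: np.random.Generator
    next_redraw: float = 0.0

    def maybe_redraw(self, system: PlanarSystem) -> bool:
        if self.sigma_omega == 0.0:
            return False
        if system.t + 1e-12 < self.next_redraw:
            return False
        system.omega = sample_frequencies(
            self.omega_bar, self.sigma_omega, system.S, self.rng)
        self.next_redraw += self.redraw_interval
        return True


# ---------------------------------------------------------------------------
# initial conditions


def _min_image(d, L):
    return d - L * np.round(d / L)


def initialize(config: SuspensionConfig, grid: GridSpec,
               params: PhysicalParams, *, n_flag: int = 29,
               max_tries: int = 2000) -> PlanarSystem:
    """Build the initial system state for the requested mode.

    Deterministic given the seeds in ``config``.  Polar mode places the
    swimmers on a jittered lattice (guaranteeing non-overlap at start),
    all pointing along +x so that they swim in -x; isotropic mode draws
    uniform random positions and orientations, rejecting head placements
    closer than one head diameter.  Pair mode puts two parallel swimmers
    at the configured offset with an imposed phase difference delta_phi.
    """
    place = np.random.default_rng(config.placement_seed)
    phase = np.random.default_rng(config.phase_seed)
    freq = np.random.default_rng(config.freq_seed)
    N, L = config.N, grid.L

    if config.init_mode == "solitary":
        system = PlanarSystem.solitary(params, grid, n_flag=n_flag)
        system.phi[:] = 0.0

    elif config.init_mode == "pair":
        off = np.asarray(config.pair_offset, dtype=float) * params.d
        s1 = straight_swimmer(params, n_flag, theta=0.0, phi=0.0)
        s2 = straight_swimmer(params, n_flag, theta=0.0,
                              phi=config.delta_phi)
        system = PlanarSystem.from_swimmers([s1, s2], params, grid)
        center = np.array([L / 2, L / 2])
        system.x[0] += center - system.x[0].mean(axis=0)
        system.x[1] += center + off - system.x[1].mean(axis=0)

    elif config.init_mode == "polar":
        # lanes of head-to-tail swimmers: an overlap-free aligned state
        # exists for any area fraction the lane geometry admits, because
        # the swimmers are thin rods
        width = params.d + 3 * params.b          # body extent plus margin
        per_row = max(int(L // width), 1)
        n_rows = int(np.ceil(N / per_row))
        row_gap = L / n_rows
        min_gap = 2 * (params.a + params.b)
        if row_gap < min_gap:
            raise RuntimeError(
                f"cannot place {N} aligned swimmers without overlap: lane "
                f"spacing {row_gap:.2f} < {min_gap:.2f}; enlarge L or lower N")
        cell = L / per_row
        yjit_max = max(0.0, 0.45 * (row_gap - min_gap))
        swimmers = []
        for m, ph in enumerate(phase.uniform(0, 2 * np.pi, N)):
            row, col = divmod(m, per_row)
            jx = place.uniform(0.0, max(cell - width, 0.0))
            jy = place.uniform(-yjit_max, yjit_max)
            sw = straight_swimmer(params, n_flag, theta=0.0, phi=float(ph))
            # head surface at the jittered offset within the cell
            sw.pos[:, 0] += col * cell + jx + params.a - sw.pos[0, 0]
            sw.pos[:, 1] += (row + 0.5) * row_gap + jy
            swimmers.append(sw)
        system = PlanarSystem.from_swimmers(swimmers, params, grid)

    else:  # isotropic
        heads = []
        tries = 0
        while len(heads) < N:
            cand = place.uniform(0, L, size=2)
            if all(np.linalg.norm(_min_image(cand - h, L)) > 2 * params.a
                   for h in heads):
                heads.append(cand)
            tries += 1
            if tries > max_tries * N:
                raise RuntimeError("could not place swimmers without "
                                   "head overlap; lower N or enlarge L")
        thetas = place.uniform(0, 2 * np.pi, N)
        swimmers = []
        for h, th, ph in zip(heads, thetas, phase.uniform(0, 2 * np.pi, N)):
            sw = straight_swimmer(params, n_flag, theta=float(th),
                                  phi=float(ph))
            sw.pos[:, :2] += h - sw.pos[0, :2]
            swimmers.append(sw)
        system = PlanarSystem.from_swimmers(swimmers, params, grid)

    system.omega = sample_frequencies(
        params.omega_bar, params.sigma_omega, system.S, freq)
    return system


# ---------------------------------------------------------------------------
# main loop


def run(system: PlanarSystem, n_periods: float, settings: SolverSettings,
        backend, *, observers=(), observe_every: int = 1,
        freq_rng: np.random.Generator | None = None,
        stepper_kwargs: dict | None = None) -> Stepper:
    """Advance the suspension for ``n_periods`` mean undulation periods.

    ``observers`` are callables ``obs(system, diagnostics)`` invoked every
    ``observe_every`` accepted steps.  When the physical parameters carry
    sigma_omega > 0, frequencies are redrawn synchronously every T using
    ``freq_rng`` (mandatory in that case, for reproducibility).
    """
    p = system.params
    proc = None
    if p.sigma_omega > 0.0:
        if freq_rng is None:
            raise ValueError("sigma_omega > 0 requires an explicit freq_rng")
        proc = FrequencyProcess(p.omega_bar, p.sigma_omega, p.T, freq_rng,
                                next_redraw=system.t + p.T)
    stepper = Stepper(system, settings, backend, **(stepper_kwargs or {}))
    n_steps = int(round(n_periods * p.T / settings.dt))
    for k in range(n_steps):
        if proc is not None:
            proc.maybe_redraw(system)
        diag = stepper.step()
        if (k + 1) % observe_every == 0:
            for obs in observers:
                obs(system, diag)
    return stepper
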
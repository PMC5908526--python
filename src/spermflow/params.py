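"""Physical and numerical parameters for thin-film swimmer suspensions.

All quantities are expressed in native simulation units in which the fluid
viscosity is eta = 1 and the flagellum segment radius is b = 1.  The default
parameter set reproduces a mammalian-sperm-like swimmer: an oblate-spheroid
head of in-plane half axis ``a`` and half height ``b = a/3`` attached to an
inextensible elastic flagellum of length ``l`` driven by a preferred-curvature
wave.  The sperm number

    Sp = (4 pi omega eta / K_B)^(1/4) * l

measures the ratio of viscous to elastic forces and, together with the
curvature amplitude ``K0 l``, fixes the flagellar waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["PhysicalParams", "GridSpec", "SolverSettings", "SuspensionConfig"]

_TWO_PI = 2.0 * math.pi


class ParameterError(ValueError):
    """A parameter block violates one of its defining identities."""


@dataclass(frozen=True)
class PhysicalParams:
    """Swimmer geometry, elasticity and actuation parameters.

    The block is over-determined on purpose: redundant quantities such as
    ``d`` (swimmer length), ``Sp`` and ``T`` are stored alongside their
    defining ingredients and validated against the identities

        d = 2.1 a + l,     Sp = (4 pi omega_bar eta / K_B)^(1/4) l,
        b = a / 3,         k_wave = 2 pi / l,      T = 2 pi / omega_bar,

    so that a hand-edited configuration cannot silently drift out of
    consistency.
    """

    eta: float          # dynamic viscosity
    K_B: float          # bending modulus
    K0: float           # preferred-curvature amplitude (1/length)
    k_wave: float       # preferred-curvature wavenumber (1/length)
    omega_bar: float    # mean undulation frequency (rad/time)
    sigma_omega: float  # frequency standard deviation (rad/time)
    Sp: float           # sperm number (dimensionless)
    a: float            # head in-plane half axis
    b: float            # segment radius = head half height
    l: float            # flagellum length
    d: float            # swimmer length = 2.1 a + l
    F_S: float          # steric force scale (force at contact)
    T: float            # mean undulation period = 2 pi / omega_bar
    dt: float           # time step
    gamma_tip: float    # fraction of l over which the curvature ramps to zero

    def __post_init__(self) -> None:
        for name in ("eta", "K_B", "K0", "k_wave", "omega_bar", "Sp", "a",
                     "b", "l", "d", "F_S", "T", "dt"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.sigma_omega < 0.0:
            raise ParameterError("sigma_omega must be non-negative")
        if not 0.0 < self.gamma_tip < 1.0:
            raise ParameterError("gamma_tip must lie in (0, 1)")
        if abs(self.d - (2.1 * self.a + self.l)) > 1e-12 * self.d:
            raise ParameterError("swimmer length must satisfy d = 2.1 a + l")
        sp = (4.0 * math.pi * self.omega_bar * self.eta / self.K_B) ** 0.25 * self.l
        if abs(sp - self.Sp) > 1e-12 * self.Sp:
            raise ParameterError(
                "Sp inconsistent with (4 pi omega eta / K_B)^(1/4) l")
        if abs(self.b - self.a / 3.0) > 1e-12 * self.b:
            raise ParameterError("head aspect ratio must satisfy b = a/3")
        if abs(self.k_wave - _TWO_PI / self.l) > 1e-12 * self.k_wave:
            raise ParameterError("wavenumber must satisfy k = 2 pi / l")
        if abs(self.T - _TWO_PI / self.omega_bar) > 1e-9 * self.T:
            raise ParameterError("period must satisfy T = 2 pi / omega_bar")

    # -- constructors -----------------------------------------------------

    @classmethod
    def build(cls, *, a: float = 3.0, d: float = 70.1, Sp: float = 12.0,
              K_B: float = 1800.0, K0_l: float = 12.76, eta: float = 1.0,
              F_S_over_d: float = 15.0 * math.pi, sigma_ratio: float = 0.0,
              steps_per_period: int = 300,
              gamma_tip: float = 0.13) -> "PhysicalParams":
        """Construct a consistent block from the independent inputs.

        ``omega_bar`` is obtained by inverting the sperm-number definition,
        omega = Sp^4 K_B / (4 pi eta l^4), and the time step is
        ``T / steps_per_period``.
        """
        l = d - 2.1 * a
        omega = Sp ** 4 * K_B / (4.0 * math.pi * eta * l ** 4)
        T = _TWO_PI / omega
        return cls(
            eta=eta, K_B=K_B, K0=K0_l / l, k_wave=_TWO_PI / l,
            omega_bar=omega, sigma_omega=sigma_ratio * omega, Sp=Sp,
            a=a, b=a / 3.0, l=l, d=d, F_S=F_S_over_d * d,
            T=T, dt=T / steps_per_period, gamma_tip=gamma_tip,
        )

    @classmethod
    def reference(cls, *, sigma_ratio: float = 0.0,
               gamma_tip: float = 0.13) -> "PhysicalParams":
        """The reference ram-sperm-like parameter set (simulation units)."""
        return cls.build(sigma_ratio=sigma_ratio, gamma_tip=gamma_tip)

    def with_(self, **kw) -> "PhysicalParams":
        return replace(self, **kw)

    # -- derived ----------------------------------------------------------

    @property
    def head_offset(self) -> float:
        """Distance from head centre to flagellum attachment point, 1.1 a.

        The extra 0.1 a over the head half axis models the neck linkage
        between head and flagellum.
        """
        return 1.1 * self.a


@dataclass(frozen=True)
class GridSpec:
    """Periodic thin-film simulation domain and fluid grid.

    The domain is a triply periodic box L x L x L_z with uniform grid
    spacing ``dx = L/N_x = L_z/N_z``.  The film is thin (L_z << L); by
    symmetry its midplane z = L_z/2 behaves like the plane of a free-surface
    liquid film, and all swimmers are confined there.
    """

    L: float
    L_z: float
    N_x: int
    N_y: int
    N_z: int

    def __post_init__(self) -> None:
        for name in ("N_x", "N_y", "N_z"):
            n = getattr(self, name)
            if n <= 0 or n % 2:
                raise ParameterError(f"{name} must be a positive even integer")
        dx = self.L / self.N_x
        if abs(self.L / self.N_y - dx) > 1e-9 * dx or \
           abs(self.L_z / self.N_z - dx) > 1e-9 * dx:
            raise ParameterError("grid spacing must be uniform: "
                                 "L/N_x = L/N_y = L_z/N_z")

    @property
    def dx(self) -> float:
        return self.L / self.N_x

    @property
    def midplane_z(self) -> float:
        return 0.5 * self.L_z

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.N_x, self.N_y, self.N_z)

    @classmethod
    def thin_film(cls, *, n_inplane: int, n_z: int = 64,
                  L_z: float = 19.40) -> "GridSpec":
        """A film of fixed thickness with the reference spacing.

        The spacing is pinned by the film discretization, dx = L_z/N_z
        (= 0.3031 for the defaults), and the in-plane extent follows as
        L = n_inplane * dx.
        """
        dx = L_z / n_z
        return cls(L=n_inplane * dx, L_z=L_z, N_x=n_inplane,
                   N_y=n_inplane, N_z=n_z)

    @classmethod
    def production(cls, *, n_inplane: int = 3072) -> "GridSpec":
        """The production film grid (L = 931.2, L_z = 19.40, dx = 0.3031)."""
        return cls.thin_film(n_inplane=n_inplane)


@dataclass(frozen=True)
class SolverSettings:
    """Time integrator and quasi-Newton solver tolerances."""

    dt: float
    broyden_tol: float = 1e-8       # scaled by sqrt(n_dof) at solve time
    broyden_maxit: int = 400
    constraint_tol_factor: float = 1e-8  # admissibility tol = factor * ds

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.broyden_tol <= 0 or self.broyden_maxit <= 0 \
                or self.constraint_tol_factor <= 0:
            raise ParameterError("solver settings must be strictly positive")

    @classmethod
    def for_params(cls, params: PhysicalParams, **kw) -> "SolverSettings":
        return cls(dt=params.dt, **kw)


_INIT_MODES = ("solitary", "polar", "isotropic", "pair")


@dataclass(frozen=True)
class SuspensionConfig:
    """Population-level configuration: counts, seeds and initial condition."""

    N: int
    init_mode: str = "polar"
    phase_seed: int = 0
    freq_seed: int = 1
    placement_seed: int = 2
    delta_phi: float = 0.0          # imposed phase difference (pair mode)
    pair_offset: tuple[float, float] = (0.0, 0.3)  # pair mode, units of d

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ParameterError("swimmer count N must be >= 1")
        if self.init_mode not in _INIT_MODES:
            raise ParameterError(f"init_mode must be one of {_INIT_MODES}")
        if self.init_mode == "pair" and self.N != 2:
            raise ParameterError("pair mode requires N = 2")
        if self.init_mode == "solitary" and self.N != 1:
            raise ParameterError("solitary mode requires N = 1")

    def area_fraction(self, params: PhysicalParams, grid: GridSpec) -> float:
        """Effective area fraction nu = N d^2 / (4 L^2)."""
        return self.N * params.d ** 2 / (4.0 * grid.L ** 2)
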
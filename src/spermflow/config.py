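"""Run configuration: TOML parsing, validation and serialization.

A run is specified by the independent inputs only — the sperm-number
block, grid shape, suspension layout, solver tolerances, backend choice
and a master seed.  Derived quantities (l, omega, T, dt, nu, dx) are
always recomputed through the parameter constructors, never stored as
independent truths, so a configuration cannot contradict itself.  The
master seed deterministically spawns the named streams used for
placement, phases and frequencies.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .params import (GridSpec, ParameterError, PhysicalParams,
                     SolverSettings, SuspensionConfig)

__all__ = ["RunConfig", "load_config", "serialize_config", "default_config"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Validated, serializable description of a simulation run."""

    backend: str = "fcm"
    master_seed: int = 0
    # physical block (independent inputs of PhysicalParams.build)
    a: float = 3.0
    d: float = 70.1
    Sp: float = 12.0
    K_B: float = 1800.0
    K0_l: float = 12.76
    eta: float = 1.0
    F_S_over_d: float = 15.0 * math.pi
    sigma_ratio: float = 0.0
    steps_per_period: int = 300
    gamma_tip: float = 0.13
    # grid block
    n_inplane: int = 3072
    n_z: int = 64
    L_z: float = 19.40
    # suspension block
    N: int = 1
    init_mode: str = "solitary"
    delta_phi: float = 0.0
    pair_offset: tuple[float, float] = (0.0, 0.3)
    # solver block
    broyden_tol: float = 1e-8
    broyden_maxit: int = 400
    constraint_tol_factor: float = 1e-8
    # output block
    n_periods: float = 30.0
    n_flag: int = 29
    snapshot_every: int = 10
    out_path: str = "trajectory.h5"

    def __post_init__(self):
        if self.backend not in ("fcm", "rft"):
            raise ParameterError("backend must be 'fcm' or 'rft'")
        # build every block so the validators run
        self.params()
        self.grid()
        self.suspension()
        self.solver()

    # -- typed blocks ------------------------------------------------------

    def params(self) -> PhysicalParams:
        return PhysicalParams.build(
            a=self.a, d=self.d, Sp=self.Sp, K_B=self.K_B, K0_l=self.K0_l,
            eta=self.eta, F_S_over_d=self.F_S_over_d,
            sigma_ratio=self.sigma_ratio,
            steps_per_period=self.steps_per_period,
            gamma_tip=self.gamma_tip)

    def grid(self) -> GridSpec:
        return GridSpec.thin_film(n_inplane=self.n_inplane, n_z=self.n_z,
                                  L_z=self.L_z)

    def seeds(self) -> dict:
        ss = np.random.SeedSequence(self.master_seed)
        placement, phase, freq = ss.generate_state(3)
        return {"placement_seed": int(placement) % (2 ** 31),
                "phase_seed": int(phase) % (2 ** 31),
                "freq_seed": int(freq) % (2 ** 31)}

    def suspension(self) -> SuspensionConfig:
        return SuspensionConfig(N=self.N, init_mode=self.init_mode,
                                delta_phi=self.delta_phi,
                                pair_offset=tuple(self.pair_offset),
                                **self.seeds())

    def solver(self) -> SolverSettings:
        return SolverSettings(
            dt=self.params().dt, broyden_tol=self.broyden_tol,
            broyden_maxit=self.broyden_maxit,
            constraint_tol_factor=self.constraint_tol_factor)

    def area_fraction(self) -> float:
        return self.suspension().area_fraction(self.params(), self.grid())

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


_BLOCKS = {
    "physical": ("a", "d", "Sp", "K_B", "K0_l", "eta", "F_S_over_d",
                 "sigma_ratio", "steps_per_period", "gamma_tip"),
    "grid": ("n_inplane", "n_z", "L_z"),
    "suspension": ("N", "init_mode", "delta_phi", "pair_offset"),
    "solver": ("broyden_tol", "broyden_maxit", "constraint_tol_factor"),
    "output": ("n_periods", "n_flag", "snapshot_every", "out_path"),
}
_TOP = ("backend", "master_seed")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Unknown keys are rejected with a field-level message; every block
    invariant is re-checked by the dataclass constructors.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kw = {}
    for key, val in raw.items():
        if key in _TOP:
            kw[key] = val
        elif key in _BLOCKS:
            for sub, sval in val.items():
                if sub not in _BLOCKS[key]:
                    raise ParameterError(f"unknown key [{key}] {sub}")
                kw[sub] = tuple(sval) if isinstance(sval, list) else sval
        else:
            raise ParameterError(f"unknown section or key: {key}")
    try:
        return RunConfig(**kw)
    except TypeError as exc:
        raise ParameterError(str(exc)) from exc


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def serialize_config(cfg: RunConfig, path=None) -> str:
    """Emit a TOML document that round-trips through :func:`load_config`."""
    d = asdict(cfg)
    lines = [f"{k} = {_fmt(d[k])}" for k in _TOP]
    for block, keys in _BLOCKS.items():
        lines.append("")
        lines.append(f"[{block}]")
        lines.extend(f"{k} = {_fmt(d[k])}" for k in keys)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def default_config() -> RunConfig:
    """The reference production configuration (full Table of parameters)."""
    return RunConfig()
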
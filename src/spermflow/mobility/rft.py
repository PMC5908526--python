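"""Resistive force theory: local anisotropic drag, no hydrodynamic coupling.

Each flagellum segment of length ds is dragged with parallel/perpendicular
coefficients xi_par, xi_perp (force per unit length per unit speed), and
resists rotation about the film normal with a local coefficient; the head
uses its Stokes translational/rotational drags.  The mobility is block
diagonal: bodies move independently of one another, so RFT suspensions
interact only through steric forces.  Default coefficients come from
slender-body theory, xi_par = 2 pi eta / (ln(l/b) - 1/2) and
xi_perp = 2 xi_par; ``calibrate_rft`` refines them so a solitary RFT
swimmer reproduces the swimming speed and waveform envelope of a reference
run made with the full hydrodynamic solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ..params import PhysicalParams
from .shapes import ellipsoid_translation_radius, ellipsoid_rotation_radius

__all__ = ["RFTCoefficients", "RFTBackend", "rft_mobility", "calibrate_rft"]


@dataclass(frozen=True)
class RFTCoefficients:
    """Local drag set (simulation units)."""

    xi_par: float        # parallel drag per unit length
    xi_perp: float       # perpendicular drag per unit length
    zeta_rot_seg: float  # rotational drag of one segment about z
    zeta_head_t: float   # head translational drag (in-plane)
    zeta_head_r: float   # head rotational drag about z

    def __post_init__(self):
        for name in ("xi_par", "xi_perp", "zeta_rot_seg",
                     "zeta_head_t", "zeta_head_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def slender_body(cls, params: PhysicalParams,
                     n_flag: int = 29) -> "RFTCoefficients":
        ds = params.l / n_flag
        log = math.log(params.l / params.b) - 0.5
        xi_par = 2.0 * math.pi * params.eta / log
        axes = (params.a, params.a, params.b)
        a_t = ellipsoid_translation_radius(axes, 0)
        a_r = ellipsoid_rotation_radius(axes, 2)
        return cls(
            xi_par=xi_par, xi_perp=2.0 * xi_par,
            # rod piece of length ds rotating about its centre
            zeta_rot_seg=2.0 * xi_par * ds ** 3 / 12.0,
            zeta_head_t=6.0 * math.pi * params.eta * a_t,
            zeta_head_r=8.0 * math.pi * params.eta * a_r ** 3,
        )

    def with_(self, **kw) -> "RFTCoefficients":
        return replace(self, **kw)


def rft_mobility(pos, theta, kindarr, F, Tz, *, coeffs: RFTCoefficients,
                 ds: float):
    """Block-diagonal planar mobility: (F, Tz) -> (U, Wz).

    Kind 0 bodies are flagellum segments with tangent from ``theta``;
    kind 1 bodies are heads (isotropic in-plane drag).
    """
    theta = np.asarray(theta, dtype=float)
    F = np.asarray(F, dtype=float)
    Tz = np.asarray(Tz, dtype=float)
    kindarr = np.asarray(kindarr)
    U = np.empty_like(F)
    Wz = np.empty_like(Tz)

    seg = kindarr == 0
    t = np.stack([np.cos(theta[seg]), np.sin(theta[seg])], axis=-1)
    fpar = np.einsum("ij,ij->i", F[seg], t)
    Fpar = fpar[:, None] * t
    Fperp = F[seg] - Fpar
    U[seg] = Fpar / (coeffs.xi_par * ds) + Fperp / (coeffs.xi_perp * ds)
    Wz[seg] = Tz[seg] / coeffs.zeta_rot_seg

    head = ~seg
    U[head] = F[head] / coeffs.zeta_head_t
    Wz[head] = Tz[head] / coeffs.zeta_head_r
    return U, Wz


class RFTBackend:
    """Mobility backend wrapping :func:`rft_mobility`."""

    def __init__(self, coeffs: RFTCoefficients, ds: float):
        self.coeffs = coeffs
        self.ds = ds

    def velocities(self, pos, theta, kindarr, F, Tz):
        return rft_mobility(pos, theta, kindarr, F, Tz,
                            coeffs=self.coeffs, ds=self.ds)


def waveform_summary(traj_lateral: np.ndarray, speeds: np.ndarray) -> dict:
    """Reference statistics used for calibration.

    ``traj_lateral`` is an (n_samples, n_bodies) array of body positions
    perpendicular to the mean swimming direction; the summary couples the
    mean speed with the rms lateral amplitude envelope along the flagellum.
    """
    amp = np.sqrt(np.mean(
        (traj_lateral - traj_lateral.mean(axis=0)) ** 2, axis=0))
    return {"mean_speed": float(np.mean(speeds)), "amplitude": amp}


def calibrate_rft(reference: dict, params: PhysicalParams, *,
                  n_flag: int = 29, n_periods: float = 6.0,
                  measure_from_period: float = 2.0,
                  x0: RFTCoefficients | None = None,
                  xatol: float = 1e-4, maxiter: int = 200) -> RFTCoefficients:
    """Fit (xi_par, xi_perp) so an RFT solitary swimmer matches a reference.

    ``reference`` is a :func:`waveform_summary` dict from a converged
    solitary run (normally FCM).  The squared mismatch of the mean speed
    and of the lateral amplitude envelope is minimized with Nelder-Mead in
    log-coefficient space; the procedure is deterministic given the
    reference.  Self-consistency (recovering the coefficients that
    generated an RFT reference) is part of the test suite.
    """
    from scipy.optimize import minimize
    from ..experiments import solitary_rft_summary

    if not np.isfinite(reference["mean_speed"]) or \
            reference["mean_speed"] <= 0:
        raise ValueError("reference run not converged: non-positive speed")

    base = x0 or RFTCoefficients.slender_body(params, n_flag)
    ref_amp = np.asarray(reference["amplitude"], dtype=float)
    scale_u = reference["mean_speed"]
    scale_a = float(np.mean(ref_amp)) or 1.0

    def objective(logxi):
        coeffs = base.with_(xi_par=math.exp(logxi[0]),
                            xi_perp=math.exp(logxi[1]))
        summ = solitary_rft_summary(
            params, coeffs, n_flag=n_flag, n_periods=n_periods,
            measure_from_period=measure_from_period)
        du = (summ["mean_speed"] - reference["mean_speed"]) / scale_u
        da = (summ["amplitude"] - ref_amp) / scale_a
        return du * du + float(np.mean(da * da))

    res = minimize(objective,
                   [math.log(base.xi_par), math.log(base.xi_perp)],
                   method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": 1e-12,
                            "maxiter": maxiter})
    return base.with_(xi_par=math.exp(res.x[0]), xi_perp=math.exp(res.x[1]))
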
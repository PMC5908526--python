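"""Stokes resistance of triaxial ellipsoids and effective sphere radii.

The cell head is an oblate spheroid with in-plane half axis ``a`` and half
height ``b = a/3``.  In the mobility solver it is represented by a single
Gaussian-envelope particle whose effective radius reproduces the analytic
edgewise (in-plane) translational drag of the spheroid; rotations about the
film normal use the analogous rotational effective radius.  The classical
Oberbeck/Jeffery results are evaluated here by quadrature:

    R_trans,i = 16 pi eta / (chi + a_i^2 alpha_i)
    R_rot,i   = 16 pi eta (a_j^2 + a_k^2) / (3 (a_j^2 alpha_j + a_k^2 alpha_k))

with chi = int_0^inf dt / Delta(t), alpha_i = int_0^inf dt / ((a_i^2+t)
Delta(t)) and Delta = sqrt(prod_i (a_i^2 + t)).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.integrate import quad

__all__ = ["ellipsoid_translation_radius", "ellipsoid_rotation_radius"]


def _delta(t: float, axes: tuple[float, float, float]) -> float:
    return float(np.sqrt(np.prod([ax * ax + t for ax in axes])))


@lru_cache(maxsize=64)
def _chi_alpha(axes: tuple[float, float, float]):
    chi = quad(lambda t: 1.0 / _delta(t, axes), 0.0, np.inf)[0]
    alpha = tuple(
        quad(lambda t: 1.0 / ((ax * ax + t) * _delta(t, axes)), 0.0, np.inf)[0]
        for ax in axes)
    return chi, alpha


def ellipsoid_translation_radius(axes, direction: int = 0) -> float:
    """Stokes-equivalent sphere radius for translation along ``axes[direction]``.

    ``axes`` are the three half axes; returns R such that the drag is
    6 pi eta R U.  For a sphere this returns its radius exactly.
    """
    axes = tuple(float(ax) for ax in axes)
    chi, alpha = _chi_alpha(axes)
    resistance = 16.0 * np.pi / (chi + axes[direction] ** 2 * alpha[direction])
    return resistance / (6.0 * np.pi)


def ellipsoid_rotation_radius(axes, axis: int = 2) -> float:
    """Stokes-equivalent sphere radius for rotation about ``axes[axis]``.

    Returns R such that the rotational drag is 8 pi eta R^3 W.
    """
    axes = tuple(float(ax) for ax in axes)
    _, alpha = _chi_alpha(axes)
    j, k = [i for i in range(3) if i != axis]
    resistance = 16.0 * np.pi * (axes[j] ** 2 + axes[k] ** 2) / (
        3.0 * (axes[j] ** 2 * alpha[j] + axes[k] ** 2 * alpha[k]))
    return (resistance / (8.0 * np.pi)) ** (1.0 / 3.0)
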
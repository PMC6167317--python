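"""Demagnetizing factors of rectangular prisms and shape-anisotropy thresholds.

Magnetofossil crystals are modelled as elongated parallelepipeds of square
cross-section (width W × width W × length L, L ≥ W).  The switching field of
such a single-domain particle is set by the difference ΔN between the
self-demagnetizing factor transverse to the elongation axis and the factor
along it (``B_sw = μ0 ΔN Ms``).  The longitudinal factor is evaluated with
the closed-form expression for a uniformly magnetized rectangular prism
(Aharoni's analytic result); for a square cross-section the transverse
factor follows from the trace identity ``Nx + Ny + Nz = 1``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .constants import MU0, MS_MAGNETITE, K1_MAGNETITE

__all__ = [
    "prism_demag_factor",
    "delta_n",
    "shape_dominance_critical_ratio",
]


def prism_demag_factor(a: float, b: float, c: float) -> float:
    """Longitudinal demagnetizing factor of a rectangular prism.

    Parameters
    ----------
    a, b, c
        Semi-axes of the prism (any consistent length unit); the factor is
        evaluated along the ``c`` axis for uniform magnetization.

    Returns
    -------
    float
        The magnetometric demagnetizing factor ``N_c`` in SI convention
        (``Nx + Ny + Nz = 1``; a cube gives exactly 1/3).
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("prism semi-axes must be positive")
    r_abc = np.sqrt(a * a + b * b + c * c)
    r_ab = np.sqrt(a * a + b * b)
    r_bc = np.sqrt(b * b + c * c)
    r_ac = np.sqrt(a * a + c * c)

    t = 0.0
    t += (b * b - c * c) / (2 * b * c) * np.log((r_abc - a) / (r_abc + a))
    t += (a * a - c * c) / (2 * a * c) * np.log((r_abc - b) / (r_abc + b))
    t += b / (2 * c) * np.log((r_ab + a) / (r_ab - a))
    t += a / (2 * c) * np.log((r_ab + b) / (r_ab - b))
    t += c / (2 * a) * np.log((r_bc - b) / (r_bc + b))
    t += c / (2 * b) * np.log((r_ac - a) / (r_ac + a))
    t += 2 * np.arctan2(a * b, c * r_abc)
    t += (a**3 + b**3 - 2 * c**3) / (3 * a * b * c)
    t += (a * a + b * b - 2 * c * c) / (3 * a * b * c) * r_abc
    t += c / (a * b) * (r_ac + r_bc)
    t -= (r_ab**3 + r_bc**3 + r_ac**3) / (3 * a * b * c)
    return float(t / np.pi)


def delta_n(length: float, width: float) -> float:
    """ΔN of a square-cross-section parallelepiped (length ≥ width).

    ΔN is the difference between the demagnetizing factors transverse to and
    along the elongation axis.  It vanishes for a cube and approaches 1/2 in
    the infinite-rod limit; the shape-anisotropy switching field of the
    particle is ``μ0 ΔN Ms``.

    Parameters
    ----------
    length, width
        Full particle dimensions in any consistent unit (nm throughout this
        package); requires ``length ≥ width > 0``.
    """
    if width <= 0 or length <= 0:
        raise ValueError("particle dimensions must be positive")
    if length < width:
        raise ValueError("length must be >= width (axial ratio <= 1)")
    if length == width:
        return 0.0
    n_long = prism_demag_factor(width / 2, width / 2, length / 2)
    n_trans = (1.0 - n_long) / 2.0
    return float(n_trans - n_long)


def shape_dominance_critical_ratio(
    ms: float = MS_MAGNETITE,
    k1: float = K1_MAGNETITE,
    bracket: tuple[float, float] = (1.0 + 1e-9, 2.0),
) -> float:
    """Length/width ratio above which shape anisotropy dominates in magnetite.

    Compares the uniaxial shape-anisotropy energy density of a slightly
    elongated particle, ``0.5 μ0 ΔN(r) Ms²``, with the effective uniaxial
    barrier arising from the cubic magnetocrystalline anisotropy of
    magnetite, ``|K1|/12`` (the barrier between adjacent easy ⟨111⟩
    directions for negative K1).  Returns the ratio ``r = length/width`` at
    which the two are equal; for larger elongations the shape term dominates
    and cubic anisotropy may be neglected.

    Parameters
    ----------
    ms
        Saturation magnetization in A/m (room-temperature magnetite default).
    k1
        First cubic anisotropy constant in J/m³ (sign is ignored).
    """
    barrier = abs(k1) / 12.0

    def f(r: float) -> float:
        return 0.5 * MU0 * delta_n(r, 1.0) * ms * ms - barrier

    lo, hi = bracket
    return float(brentq(f, lo, hi, xtol=1e-12))
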
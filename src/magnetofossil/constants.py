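"""Physical constants for single-domain magnetite modelling.

The equilibrium solver is athermal and does not integrate the
Landau–Lifshitz–Gilbert equation in time, so the gyromagnetic frequency
``GAMMA`` and damping parameter ``ALPHA`` are carried for documentation of
the underlying dynamics only and never enter the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Vacuum permeability, T·m/A.
MU0 = 4e-7 * 3.141592653589793

#: Saturation magnetization of magnetite at room temperature, A/m.
MS_MAGNETITE = 480_000.0

#: First cubic magnetocrystalline anisotropy constant of magnetite at room
#: temperature, J/m³ (negative: ⟨111⟩ easy axes).
K1_MAGNETITE = -1.1e4

#: Electron gyromagnetic ratio, rad s⁻¹ T⁻¹ (documentation only).
GAMMA = 1.76e11

#: Dimensionless Gilbert damping (documentation only).
ALPHA = 1.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of material constants used by the micromagnetic solver."""

    ms: float = MS_MAGNETITE
    mu0: float = MU0
    gamma: float = GAMMA
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if self.ms <= 0:
            raise ValueError("saturation magnetization Ms must be positive")

    @property
    def mu0_ms_mT(self) -> float:
        """μ0·Ms expressed in mT (field scale of shape anisotropy)."""
        return self.mu0 * self.ms * 1e3
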
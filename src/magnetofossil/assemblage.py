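"""Three-dimensional magnetosome chain architectures.

Magnetotactic bacteria arrange their magnetite crystals in chains; after
burial these chains persist intact, bend, or collapse.  This module builds
ensembles of single-domain (SD) particles arranged in chains whose
geometry is controlled by four knobs:

* ``particles_per_chain`` — crystals per chain;
* ``bending_factor`` b ∈ [0, 1] — a spherical random-walk rule for the
  chain axis: successive step directions are
  ``d_{i+1} = normalize((1-b)·d_i + b·u)`` with ``u`` uniform on the
  sphere, so b = 0 gives straight chains and b = 1 an isotropic random
  walk ("collapsed" chains);
* ``grain_separation`` — surface-to-surface gap along the chain axis in nm
  (centre spacing = adjacent half-lengths + gap), representing the
  magnetosome membrane spacing;
* ``packing_fraction`` — total particle volume over enclosing box volume,
  which sets the mean strength of inter-chain dipolar interactions.

Crystals are drawn with replacement from a measured (or synthetic)
population, so repeated realizations emulate repeated random sampling from
TEM observations.  Each particle's easy axis (its elongation axis) is tied
to the local chain direction, the biologically observed arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import PhysicalConstants
from .demag import delta_n
from .morphometry import CrystalMeasurement

__all__ = [
    "ChainConfig",
    "ChainAssemblage",
    "build_assemblage",
    "resample_assemblage",
    "fibonacci_sphere",
    "oriented_ensemble",
]

#: ΔN assigned to effectively equant particles (length/width < 1.001) so
#: that their switching field is tiny but their easy axis stays defined.
EQUANT_DELTA_N_FLOOR = 1e-4


@dataclass(frozen=True)
class ChainConfig:
    particles_per_chain: int
    n_chains: int
    bending_factor: float = 0.0
    grain_separation: float = 20.0  # nm, surface-to-surface along the chain
    packing_fraction: float = 0.001
    orientation: str = "random"
    seed: int = 0
    equant_floor: float | None = EQUANT_DELTA_N_FLOOR

    def __post_init__(self) -> None:
        if self.particles_per_chain < 1:
            raise ValueError("particles_per_chain must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (0 <= self.bending_factor <= 1):
            raise ValueError("bending_factor must lie in [0, 1]")
        if self.grain_separation < 0:
            raise ValueError("grain_separation must be >= 0")
        if not (0 < self.packing_fraction < 1):
            raise ValueError("packing_fraction must lie in (0, 1)")
        if self.orientation != "random":
            raise ValueError("only random chain orientation is supported")


@dataclass
class ChainAssemblage:
    """Arrays describing every SD particle of a chain ensemble.

    Positions and sizes in nm; ``volumes = length × width²`` (square
    cross-section parallelepipeds); ``b_sw`` is the per-particle
    Stoner–Wohlfarth switching field μ0·ΔN·Ms in mT.
    """

    positions: np.ndarray  # (N, 3) nm
    easy_axes: np.ndarray  # (N, 3) unit vectors
    lengths: np.ndarray  # (N,) nm
    widths: np.ndarray  # (N,) nm
    chain_ids: np.ndarray  # (N,) int
    box_side: float  # nm
    config: ChainConfig
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    population: list[CrystalMeasurement] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.volumes = self.lengths * self.widths**2
        floor = self.config.equant_floor
        dn = np.empty(len(self.lengths))
        for i, (ell, w) in enumerate(zip(self.lengths, self.widths)):
            if ell / w < 1.001:
                if floor is None:
                    raise ValueError(
                        "effectively equant particle (length/width < 1.001) has no "
                        "shape anisotropy; set an equant_floor to proceed"
                    )
                dn[i] = floor
            else:
                dn[i] = delta_n(ell, w)
        self.delta_n = dn
        # switching field μ0·ΔN·Ms in mT
        self.b_sw = self.constants.mu0_ms_mT * dn

    @property
    def n_particles(self) -> int:
        return len(self.lengths)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())


def _uniform_sphere(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _chain_geometry(
    lengths: np.ndarray, separation: float, bending: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Local chain coordinates: particle centres and per-particle axes."""
    n = len(lengths)
    d = _uniform_sphere(rng)[0]
    positions = np.zeros((n, 3))
    axes = np.zeros((n, 3))
    axes[0] = d
    for i in range(1, n):
        if bending > 0:
            u = _uniform_sphere(rng)[0]
            d_new = (1 - bending) * d + bending * u
            norm = np.linalg.norm(d_new)
            while norm < 1e-12:  # antipodal degenerate draw
                u = _uniform_sphere(rng)[0]
                d_new = (1 - bending) * d + bending * u
                norm = np.linalg.norm(d_new)
            d = d_new / norm
        spacing = 0.5 * lengths[i - 1] + 0.5 * lengths[i] + separation
        positions[i] = positions[i - 1] + spacing * d
        axes[i] = d
    return positions, axes


def build_assemblage(
    crystals: list[CrystalMeasurement],
    config: ChainConfig,
    constants: PhysicalConstants | None = None,
    max_retries: int = 10_000,
) -> ChainAssemblage:
    """Assemble randomly drawn crystals into randomly placed chains.

    Crystals are sampled with replacement from ``crystals``.  Chains are
    built with the bending-factor random walk, then dropped with uniform
    random position (first particle anywhere in the box) and orientation
    into a cubic box sized so that total particle volume / box volume
    equals ``config.packing_fraction``.  Chains may protrude through the
    box faces but may not approach each other closer than one minimum
    particle width (centre-to-centre, between different chains); placement
    is by rejection sampling with at most ``max_retries`` attempts per
    chain.
    """
    if not crystals:
        raise ValueError("crystal population is empty")
    constants = constants or PhysicalConstants()
    rng = np.random.default_rng(config.seed)
    n_total = config.particles_per_chain * config.n_chains
    idx = rng.integers(0, len(crystals), size=n_total)
    lengths = np.array([crystals[i].length for i in idx])
    widths = np.array([crystals[i].width for i in idx])

    volumes = lengths * widths**2
    box_side = float((volumes.sum() / config.packing_fraction) ** (1 / 3))
    min_dist = float(widths.min())

    positions = np.zeros((n_total, 3))
    axes = np.zeros((n_total, 3))
    chain_ids = np.repeat(np.arange(config.n_chains), config.particles_per_chain)
    placed: list[np.ndarray] = []
    for c in range(config.n_chains):
        sl = slice(c * config.particles_per_chain, (c + 1) * config.particles_per_chain)
        local_pos, local_axes = _chain_geometry(
            lengths[sl], config.grain_separation, config.bending_factor, rng
        )
        ok = False
        for _ in range(max_retries):
            origin = rng.uniform(0, box_side, size=3)
            candidate = local_pos + origin
            if placed:
                other = np.vstack(placed)
                d2 = ((candidate[:, None, :] - other[None, :, :]) ** 2).sum(-1)
                if d2.min() < min_dist**2:
                    continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place chain {c} without overlap after "
                f"{max_retries} retries (packing_fraction too high?)"
            )
        positions[sl] = candidate
        axes[sl] = local_axes
        placed.append(candidate)

    return ChainAssemblage(
        positions=positions,
        easy_axes=axes,
        lengths=lengths,
        widths=widths,
        chain_ids=chain_ids,
        box_side=box_side,
        config=config,
        constants=constants,
        population=list(crystals),
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly-equidistributed unit vectors (spherical Fibonacci lattice).

    Used for isotropic-orientation quadrature: when comparing ensemble
    averages against closed-form results for randomly oriented particles,
    the lattice removes Monte-Carlo orientation noise (O(1/n) error instead
    of O(1/√n)).
    """
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def oriented_ensemble(
    length: float,
    width: float,
    axes: np.ndarray,
    packing_fraction: float = 1e-6,
    constants: PhysicalConstants | None = None,
) -> ChainAssemblage:
    """Ensemble of identical isolated particles with prescribed easy axes.

    Particles are placed on a widely spaced cubic lattice (the packing
    fraction default makes dipolar coupling negligible); intended for
    oracle comparisons against single-particle Stoner–Wohlfarth theory.
    """
    axes = np.asarray(axes, dtype=float)
    n = len(axes)
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    volume = length * width**2
    box_side = float((n * volume / packing_fraction) ** (1 / 3))
    per_side = int(np.ceil(n ** (1 / 3)))
    step = box_side / per_side
    k = np.arange(per_side)
    gx, gy, gz = np.meshgrid(k, k, k, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])[:n] * step + step / 2
    cfg = ChainConfig(
        particles_per_chain=1, n_chains=n, packing_fraction=packing_fraction
    )
    return ChainAssemblage(
        positions=grid.astype(float),
        easy_axes=axes,
        lengths=np.full(n, float(length)),
        widths=np.full(n, float(width)),
        chain_ids=np.arange(n),
        box_side=box_side,
        config=cfg,
        constants=constants or PhysicalConstants(),
    )


def resample_assemblage(assemblage: ChainAssemblage, seed: int) -> ChainAssemblage:
    """Re-draw particles and geometry with the same configuration.

    Emulates selecting particles randomly again from the observed
    population for each repeated simulation.
    """
    if assemblage.population is None:
        raise ValueError("assemblage does not retain its source population")
    cfg = replace(assemblage.config, seed=seed)
    return build_assemblage(assemblage.population, cfg, assemblage.constants)
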
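"""Equilibrium magnetization of interacting SD ensembles and field protocols.

The solver follows the rapid approximate scheme used for biogenic magnetite
assemblages: rather than integrating the Landau–Lifshitz–Gilbert equation in
time, the ensemble is relaxed iteratively — each particle's moment is placed
at the Stoner–Wohlfarth energy minimum (uniaxial shape anisotropy with
switching field ``B_sw = μ0·ΔN·Ms``) nearest its current orientation, in the
plane spanned by its easy axis and the local field (applied + dipolar field
from all other particles), and the sweep repeats until the maximum angular
update falls below tolerance.  The model is athermal (0 K): hysteresis
arises purely from the history-dependent choice of energy well.

Dipolar interactions are exact all-pairs sums, evaluated through a dense
precomputed 3N×3N coupling matrix (assemblages here are at most a few
thousand particles).  Cubic magnetocrystalline anisotropy is neglected,
appropriate for magnetite elongated beyond a length/width ratio ≈ 1.02
where shape anisotropy dominates (see :mod:`magnetofossil.demag`).

Field protocols (major hysteresis loop, backfield remanence, first-order
reversal curves) carry the moment state from step to step, as a vibrating
sample magnetometer would.  All fields are reported as B = μ0·H in mT;
magnetization is normalized by ensemble saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assemblage import ChainAssemblage, resample_assemblage

__all__ = [
    "FieldProtocol",
    "MomentState",
    "ForcDataset",
    "HysteresisResult",
    "dipole_matrix",
    "switching_field",
    "relax",
    "total_energy",
    "run_hysteresis",
    "run_forc",
]

_N_GRID = 72  # coarse angular grid; the SW energy has at most two minima


@dataclass(frozen=True)
class FieldProtocol:
    """Field sequence specification.

    For FORC protocols the (Bc, Bu) window {Bc ≤ bc_max, |Bu| ≤ bu_max}
    is covered by reversal fields Ba ∈ [−(bc_max+bu_max), +bu_max] and
    measurement fields Bb ∈ [Ba, bc_max+bu_max] on a common lattice whose
    spacing is set by ``n_forcs``; the lattice is anchored on zero field so
    the Bb = 0 backfield column exists exactly.
    """

    kind: str = "hysteresis"  # hysteresis | backfield | forc
    saturation_field: float = 300.0  # mT
    field_step: float = 2.0  # mT (hysteresis/backfield sweeps)
    n_forcs: int = 100
    bc_max: float = 160.0  # mT
    bu_max: float = 60.0  # mT

    def __post_init__(self) -> None:
        if self.kind not in ("hysteresis", "backfield", "forc"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.saturation_field <= 0 or self.field_step <= 0:
            raise ValueError("fields must be positive")
        if self.n_forcs < 2:
            raise ValueError("n_forcs must be >= 2")

    def forc_lattice(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(reversal fields Ba, full Bb lattice, step δ) for a FORC run."""
        span = self.bc_max + 2 * self.bu_max
        delta = span / (self.n_forcs - 1)
        m_hi = round(self.bu_max / delta)
        m_lo = round(-(self.bc_max + self.bu_max) / delta)
        ba = delta * np.arange(m_hi, m_lo - 1, -1)
        m_bb = round((self.bc_max + self.bu_max) / delta)
        bb = delta * np.arange(m_lo, m_bb + 1)
        if self.saturation_field <= ba.max() + self.bc_max / 2:
            raise ValueError("saturation_field too low for the requested FORC window")
        return ba, bb, delta


@dataclass
class MomentState:
    """Unit moment vectors of every particle plus solver bookkeeping."""

    moments: np.ndarray  # (N, 3) unit vectors
    applied_field: np.ndarray  # (3,) mT
    converged: bool = True
    iterations: int = 0

    def copy(self) -> "MomentState":
        return MomentState(
            self.moments.copy(), self.applied_field.copy(), self.converged, self.iterations
        )


@dataclass
class HysteresisResult:
    field_mT: np.ndarray  # descending then ascending branch
    magnetization: np.ndarray  # normalized, along the field axis
    branch: np.ndarray  # -1 descending, +1 ascending
    bc_mT: float
    mrs_over_ms: float
    bcr_mT: float | None = None
    backfield: tuple[np.ndarray, np.ndarray] | None = None  # (B reversal, remanence)


@dataclass
class ForcDataset:
    """Raw FORC grid M(Ba, Bb), normalized by saturation.

    ``magnetization[i, j]`` is valid where ``bb[j] >= ba[i]`` (NaN
    elsewhere).  Both axes share the same field step.
    """

    ba: np.ndarray  # (nA,) reversal fields, descending
    bb: np.ndarray  # (nB,) measurement fields, ascending
    magnetization: np.ndarray  # (nA, nB), NaN where bb < ba
    metadata: dict = field(default_factory=dict)

    @property
    def field_step(self) -> float:
        return float(np.abs(np.diff(self.bb)).mean())


def switching_field(assemblage_or_delta_n, constants=None) -> np.ndarray | float:
    """Stoner–Wohlfarth switching field μ0·ΔN·Ms in mT.

    Accepts a :class:`ChainAssemblage` (returns the per-particle array) or
    a bare ΔN value with an optional constants bundle.
    """
    if isinstance(assemblage_or_delta_n, ChainAssemblage):
        return assemblage_or_delta_n.b_sw
    from .constants import PhysicalConstants

    constants = constants or PhysicalConstants()
    return constants.mu0_ms_mT * float(assemblage_or_delta_n)


def dipole_matrix(assemblage: ChainAssemblage) -> np.ndarray:
    """Dense coupling matrix A (3N×3N) with fields in mT per unit moment.

    The dipolar field at particle i is ``(A @ m.ravel()).reshape(N, 3)``
    where m holds unit moment directions; the particle moment magnitudes
    (Ms × volume) are folded into A.
    """
    pos = assemblage.positions
    n = assemblage.n_particles
    pref = assemblage.constants.mu0_ms_mT / (4 * np.pi)  # mT per (nm³/nm³)
    r = pos[:, None, :] - pos[None, :, :]  # r_i - r_j
    d = np.linalg.norm(r, axis=2)
    np.fill_diagonal(d, np.inf)
    rhat = r / d[:, :, None]
    # T_ij = pref * V_j / d³ * (3 r̂ r̂ᵀ − I)
    outer = 3 * rhat[:, :, :, None] * rhat[:, :, None, :] - np.eye(3)
    scale = pref * assemblage.volumes[None, :] / d**3
    blocks = scale[:, :, None, None] * outer
    return blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def _sw_update(
    m: np.ndarray, b_loc: np.ndarray, axes: np.ndarray, b_sw: np.ndarray
) -> np.ndarray:
    """Vectorized per-particle Stoner–Wohlfarth minimization.

    Works in the plane spanned by the easy axis and the local field; the
    reduced energy e(θ) = sin²θ/2 − h∥cosθ − h⊥sinθ has at most two minima,
    located on a 5° grid and polished by guarded Newton steps.  The minimum
    nearest the current orientation is retained (hysteresis; at an exact
    switching bifurcation the current well wins).
    """
    h = b_loc / b_sw[:, None]
    h_par = np.einsum("ij,ij->i", h, axes)
    perp = h - h_par[:, None] * axes
    h_perp = np.linalg.norm(perp, axis=1)

    # in-plane second basis vector: field's transverse direction, falling
    # back to the moment's own transverse component when the field is axial
    e2 = np.where(h_perp[:, None] > 1e-12, perp, m - np.einsum("ij,ij->i", m, axes)[:, None] * axes)
    e2n = np.linalg.norm(e2, axis=1)
    degenerate = e2n < 1e-12  # moment and field both along the easy axis
    if np.any(degenerate):
        # any perpendicular direction will do: the minimum is on the axis
        deg_axes = axes[degenerate]
        ref = np.zeros_like(deg_axes)
        ref[:, 0] = 1.0
        alt = np.cross(deg_axes, ref)
        bad = np.linalg.norm(alt, axis=1) < 1e-6
        if np.any(bad):
            ref2 = np.zeros_like(ref)
            ref2[:, 1] = 1.0
            alt[bad] = np.cross(deg_axes[bad], ref2[bad])
        e2[degenerate] = alt
        e2n = np.linalg.norm(e2, axis=1)
    e2 = e2 / e2n[:, None]

    theta0 = np.arctan2(np.einsum("ij,ij->i", m, e2), np.einsum("ij,ij->i", m, axes))

    t = np.linspace(0, 2 * np.pi, _N_GRID, endpoint=False)
    energy = (
        0.25 * (1 - np.cos(2 * t))[None, :]
        - h_par[:, None] * np.cos(t)[None, :]
        - h_perp[:, None] * np.sin(t)[None, :]
    )
    is_min = (energy < np.roll(energy, 1, axis=1)) & (energy <= np.roll(energy, -1, axis=1))
    dist = np.abs((t[None, :] - theta0[:, None] + np.pi) % (2 * np.pi) - np.pi)
    dist = np.where(is_min, dist, np.inf)
    theta = t[np.argmin(dist, axis=1)]

    step_cap = 2 * np.pi / _N_GRID
    for _ in range(8):
        g = 0.5 * np.sin(2 * theta) + h_par * np.sin(theta) - h_perp * np.cos(theta)
        gg = np.cos(2 * theta) + h_par * np.cos(theta) + h_perp * np.sin(theta)
        step = -g / np.where(np.abs(gg) > 1e-9, gg, 1e-9)
        step = np.clip(step, -step_cap, step_cap)
        step = np.where(gg > 0, step, 0.0)  # never walk toward a maximum
        theta = theta + step

    return np.cos(theta)[:, None] * axes + np.sin(theta)[:, None] * e2


def relax(
    assemblage: ChainAssemblage,
    applied_field: np.ndarray,
    initial: MomentState | None = None,
    tolerance: float = 1e-4,
    max_iter: int = 1000,
    interactions: np.ndarray | bool | None = True,
    damping: float = 0.7,
) -> MomentState:
    """Relax the ensemble to an equilibrium configuration.

    ``interactions`` may be True (build the dipole matrix), False/None
    (non-interacting ensemble), or a precomputed matrix from
    :func:`dipole_matrix` (recommended inside field sweeps).  The result is
    history-dependent: each particle stays in its current energy well until
    the well disappears.

    ``damping`` mixes each synchronous sweep with the previous state
    (``m ← normalize(m + damping·(m_sw − m))``), suppressing the two-cycle
    oscillations the undamped sweep develops under strong dipolar
    coupling; convergence is still judged on the undamped update angle, so
    the fixed point is unchanged.
    """
    b_app = np.asarray(applied_field, dtype=float)
    if not np.all(np.isfinite(b_app)):
        raise ValueError("applied field contains non-finite components")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    n = assemblage.n_particles
    if n == 0:
        raise ValueError("assemblage is empty")

    if interactions is True:
        amat = dipole_matrix(assemblage)
    elif interactions is False or interactions is None:
        amat = None
    else:
        amat = interactions

    if initial is None:
        norm = np.linalg.norm(b_app)
        m = (
            np.tile(b_app / norm, (n, 1))
            if norm > 0
            else assemblage.easy_axes.copy()
        )
    else:
        m = initial.moments.copy()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if amat is not None:
            b_loc = b_app[None, :] + (amat @ m.ravel()).reshape(n, 3)
        else:
            b_loc = np.broadcast_to(b_app, (n, 3))
        m_new = _sw_update(m, b_loc, assemblage.easy_axes, assemblage.b_sw)
        ang = np.arccos(np.clip(np.einsum("ij,ij->i", m, m_new), -1.0, 1.0))
        if amat is not None and damping < 1.0:
            m_mix = m + damping * (m_new - m)
            m = m_mix / np.linalg.norm(m_mix, axis=1, keepdims=True)
        else:
            m = m_new
        if ang.max() < tolerance:
            m = m_new
            converged = True
            break
        if amat is None:  # independent particles: one sweep is exact
            converged = True
            break
    return MomentState(moments=m, applied_field=b_app, converged=converged, iterations=it)


def total_energy(
    assemblage: ChainAssemblage,
    moments: np.ndarray,
    applied_field: np.ndarray,
    amat: np.ndarray | None = None,
) -> float:
    """Total energy (Zeeman + uniaxial shape anisotropy + dipolar).

    Arbitrary but consistent units (mT · nm³ relative-moment units);
    suitable for comparing nearby configurations.
    """
    v = assemblage.volumes
    b_app = np.asarray(applied_field, dtype=float)
    cos_axis = np.einsum("ij,ij->i", moments, assemblage.easy_axes)
    e_anis = float(np.sum(0.5 * assemblage.b_sw * v * (1 - cos_axis**2)))
    e_zee = -float(np.sum(v * (moments @ b_app)))
    e_dip = 0.0
    if amat is not None:
        b_dip = (amat @ moments.ravel()).reshape(-1, 3)
        e_dip = -0.5 * float(np.sum(v * np.einsum("ij,ij->i", moments, b_dip)))
    return e_anis + e_zee + e_dip


def _projected_m(assemblage: ChainAssemblage, state: MomentState, axis: np.ndarray) -> float:
    w = assemblage.volumes
    return float((w * (state.moments @ axis)).sum() / w.sum())


def _zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    """Linear interpolation of the first sign change of y along x."""
    s = np.sign(y)
    idx = np.where(np.diff(s) != 0)[0]
    if idx.size == 0:
        raise ValueError("no zero crossing bracketed; field grid too coarse or range too small")
    i = idx[0]
    x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def run_hysteresis(
    assemblage: ChainAssemblage,
    protocol: FieldProtocol | None = None,
    interactions: bool = True,
    compute_bcr: bool | None = None,
    tolerance: float = 1e-4,
    max_iter: int = 1000,
) -> HysteresisResult:
    """Major hysteresis loop along ẑ, with bulk parameters.

    Sweeps saturation → −saturation → saturation carrying state; reports
    Bc (descending-branch zero crossing, linearly interpolated), Mrs/Ms
    (zero-field descending remanence) and, for backfield protocols or when
    ``compute_bcr`` is set, Bcr from the backfield remanence zero crossing.
    """
    protocol = protocol or FieldProtocol()
    if protocol.kind not in ("hysteresis", "backfield"):
        raise ValueError("protocol kind must be hysteresis or backfield")
    if compute_bcr is None:
        compute_bcr = protocol.kind == "backfield"
    axis = np.array([0.0, 0.0, 1.0])
    amat = dipole_matrix(assemblage) if interactions else None

    bsat, step = protocol.saturation_field, protocol.field_step
    down = np.arange(bsat, -bsat - step / 2, -step)
    up = np.arange(-bsat, bsat + step / 2, step)

    state = relax(assemblage, bsat * axis, None, tolerance, max_iter, amat)
    fields, mags, branch = [], [], []
    backfield_b, backfield_m = [], []
    for b in down:
        state = relax(assemblage, b * axis, state, tolerance, max_iter, amat)
        fields.append(b)
        mags.append(_projected_m(assemblage, state, axis))
        branch.append(-1)
        if compute_bcr and b < 0:
            rem = relax(assemblage, 0.0 * axis, state.copy(), tolerance, max_iter, amat)
            backfield_b.append(-b)
            backfield_m.append(_projected_m(assemblage, rem, axis))
    for b in up:
        state = relax(assemblage, b * axis, state, tolerance, max_iter, amat)
        fields.append(b)
        mags.append(_projected_m(assemblage, state, axis))
        branch.append(+1)

    fields = np.array(fields)
    mags = np.array(mags)
    branch = np.array(branch)
    desc = branch == -1
    bc = -_zero_crossing(fields[desc], mags[desc])
    mrs = float(np.interp(0.0, fields[desc][::-1], mags[desc][::-1]))
    msat = mags[0]
    bcr = None
    bf = None
    if compute_bcr:
        bf_b = np.array(backfield_b)
        bf_m = np.array(backfield_m)
        bcr = _zero_crossing(bf_b, bf_m)
        bf = (bf_b, bf_m)
    return HysteresisResult(
        field_mT=fields,
        magnetization=mags / abs(msat),
        branch=branch,
        bc_mT=bc,
        mrs_over_ms=mrs / abs(msat),
        bcr_mT=bcr,
        backfield=bf,
    )


def run_forc(
    assemblage: ChainAssemblage,
    protocol: FieldProtocol,
    n_realizations: int = 1,
    seed: int = 0,
    interactions: bool = True,
    tolerance: float = 1e-4,
    max_iter: int = 1000,
    bb_max: float | None = None,
) -> ForcDataset:
    """Simulate a first-order reversal curve (FORC) measurement.

    For each realization the assemblage geometry and particle draw are
    refreshed (:func:`resample_assemblage`), the ensemble is saturated and
    stepped down the descending branch; at every reversal field Ba a FORC
    is measured by sweeping Bb back up to the maximum field, carrying
    state.  Grids are averaged pointwise over realizations and normalized
    by the saturation magnetization.

    ``bb_max`` optionally truncates every reversal curve at a lower
    maximum measurement field (e.g. ``bb_max=0`` simulates just the
    portion of the grid needed for backfield-profile extraction, at a
    fraction of the cost); the lattice itself is unchanged.
    """
    if protocol.kind != "forc":
        raise ValueError("protocol kind must be 'forc'")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    ba, bb, delta = protocol.forc_lattice()
    axis = np.array([0.0, 0.0, 1.0])
    n_a, n_b = len(ba), len(bb)
    acc = np.zeros((n_a, n_b))
    touched = np.zeros((n_a, n_b), dtype=bool)
    rng = np.random.default_rng(seed)

    for r in range(n_realizations):
        asm = assemblage if (n_realizations == 1 and r == 0) else resample_assemblage(
            assemblage, int(rng.integers(0, 2**31 - 1))
        )
        amat = dipole_matrix(asm) if interactions else None
        state = relax(asm, protocol.saturation_field * axis, None, tolerance, max_iter, amat)
        msat = abs(_projected_m(asm, state, axis))
        grid = np.full((n_a, n_b), np.nan)
        # descending branch from saturation through the Ba lattice
        pre = np.arange(protocol.saturation_field, ba[0], -delta)[1:]
        for b in pre:
            state = relax(asm, b * axis, state, tolerance, max_iter, amat)
        j_hi = n_b if bb_max is None else int(np.searchsorted(bb, bb_max + delta / 2))
        for i, b_rev in enumerate(ba):
            state = relax(asm, b_rev * axis, state, tolerance, max_iter, amat)
            j0 = int(round((b_rev - bb[0]) / delta))
            forc_state = state.copy()
            for j in range(j0, max(j0 + 1, j_hi)):
                forc_state = relax(asm, bb[j] * axis, forc_state, tolerance, max_iter, amat)
                grid[i, j] = _projected_m(asm, forc_state, axis) / msat
        acc += np.nan_to_num(grid, nan=0.0)
        touched |= ~np.isnan(grid)

    out = np.where(touched, acc / n_realizations, np.nan)
    meta = {
        "n_realizations": n_realizations,
        "seed": seed,
        "interactions": bool(interactions),
        "field_step_mT": delta,
        "protocol": {
            "saturation_field": protocol.saturation_field,
            "n_forcs": protocol.n_forcs,
            "bc_max": protocol.bc_max,
            "bu_max": protocol.bu_max,
        },
    }
    return ForcDataset(ba=ba, bb=bb, magnetization=out, metadata=meta)
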
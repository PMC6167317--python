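"""Bulk rock-magnetic proxies, down-core profiles, and low-temperature curves.

Conventions:

* ``S-ratio = −IRM₋₀.₃T / IRM₁T`` — fraction of the remanence carried by
  minerals saturating below 0.3 T (soft, e.g. magnetite); 1 for a fully
  soft assemblage.
* ``HIRM = (IRM₁T − IRM₋₀.₃T)/2`` — absolute remanence of the hard
  (e.g. haematite) fraction.  IRM at −0.3 T is a *signed* backfield
  remanence (negative when the soft fraction dominates).
* Carbonate-free basis: concentration-dependent values divided by the
  non-carbonate mass fraction ``(1 − carbonate_fraction)``, removing
  dilution by biogenic carbonate.

Low-temperature SIRM curves (ZFC/FC warming, low-temperature cycling) are
normalized per the convention recorded on the curve, and crystallographic
transitions (Verwey ~100–120 K for magnetite, Morin ~250–260 K for
haematite) are located as extrema of dM/dT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProxyRecord",
    "LowTempCurve",
    "TransitionDetection",
    "s_ratio",
    "hirm",
    "carbonate_free",
    "normalize_lowtemp",
    "detect_transition",
    "assemble_profile",
    "VERWEY_WINDOW",
    "MORIN_WINDOW",
]

#: Default search windows (K) for the two diagnostic transitions.
VERWEY_WINDOW = (90.0, 130.0)
MORIN_WINDOW = (240.0, 270.0)


@dataclass
class ProxyRecord:
    """Per-depth magnetic proxies; missing inputs stay None."""

    depth_mcd: float
    irm_1T: float | None = None
    irm_m0p3T: float | None = None  # signed backfield remanence at −0.3 T
    carbonate_fraction: float | None = None
    ms: float | None = None
    mrs_over_ms: float | None = None
    bc_mT: float | None = None
    bcr_mT: float | None = None
    biogenic_b_half_mT: float | None = None
    biogenic_dp: float | None = None
    biogenic_fraction: float | None = None


@dataclass
class LowTempCurve:
    temperature_K: np.ndarray
    moment: np.ndarray
    treatment: str  # ZFC | FC | LTC_cooling | LTC_warming
    normalization: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.temperature_K.size != self.moment.size:
            raise ValueError("temperature and moment must have equal length")
        dt = np.diff(self.temperature_K)
        if not (np.all(dt > 0) or np.all(dt < 0)):
            raise ValueError("temperatures must be monotone within a branch")


@dataclass
class TransitionDetection:
    temperature_K: float
    boundary_warning: bool = False


def s_ratio(irm_1T: float, irm_m0p3T: float) -> float:
    """S-ratio = −IRM₋₀.₃T / IRM₁T."""
    if irm_1T == 0:
        raise ValueError("IRM at 1 T must be non-zero")
    return -irm_m0p3T / irm_1T


def hirm(irm_1T: float, irm_m0p3T: float) -> float:
    """HIRM = (IRM₁T − |IRM₋₀.₃T|)/2.

    The remanence carried by minerals that resist a 0.3 T backfield.  The
    absolute value makes the result independent of whether the backfield
    remanence is passed signed (the convention used throughout this
    package) or as a magnitude: a fully soft assemblage
    (IRM₋₀.₃T = −IRM₁T) has HIRM = 0 under either convention.
    """
    return (irm_1T - abs(irm_m0p3T)) / 2.0


def carbonate_free(value: float, carbonate_fraction: float) -> float:
    """Value per unit non-carbonate mass: value / (1 − carbonate_fraction)."""
    if not (0 <= carbonate_fraction < 1):
        raise ValueError("carbonate_fraction must lie in [0, 1)")
    return value / (1.0 - carbonate_fraction)


def normalize_lowtemp(
    curve: LowTempCurve,
    reference_curve: LowTempCurve | None = None,
    reference_temperature: float = 10.0,
    tolerance_K: float = 2.0,
) -> LowTempCurve:
    """Normalize a low-temperature curve to a reference moment.

    The reference is the moment of ``reference_curve`` (default: the curve
    itself) at the measurement point nearest ``reference_temperature``;
    raises if no point lies within ``tolerance_K``.  Typical conventions:
    ZFC/FC warming normalized to the FC moment at 10 K; low-temperature
    cycling normalized to the initial room-temperature SIRM.
    """
    ref = reference_curve if reference_curve is not None else curve
    idx = int(np.argmin(np.abs(ref.temperature_K - reference_temperature)))
    if abs(ref.temperature_K[idx] - reference_temperature) > tolerance_K:
        raise ValueError(
            f"no reference point within {tolerance_K} K of {reference_temperature} K"
        )
    ref_val = ref.moment[idx]
    if ref_val == 0:
        raise ValueError("reference moment is zero")
    return LowTempCurve(
        temperature_K=curve.temperature_K.copy(),
        moment=curve.moment / ref_val,
        treatment=curve.treatment,
        normalization=f"{ref.treatment}@{ref.temperature_K[idx]:g}K",
        metadata=dict(curve.metadata),
    )


def detect_transition(
    curve: LowTempCurve, window: tuple[float, float] = VERWEY_WINDOW
) -> TransitionDetection:
    """Locate a phase transition as the extremum of dM/dT in a window.

    The discrete extremum of |dM/dT| is refined by a local quadratic fit
    through its three surrounding points.  If the extremum sits on the
    window boundary (no interior peak, e.g. a featureless curve) the
    boundary temperature is returned with a warning flag.  The result is
    invariant to multiplicative rescaling of the curve.
    """
    lo, hi = window
    order = np.argsort(curve.temperature_K)
    t = curve.temperature_K[order]
    m = curve.moment[order]
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 5:
        raise ValueError("need at least 5 points inside the detection window")
    dmdt = np.gradient(m, t)
    tw, dw = t[sel], np.abs(dmdt[sel])
    if np.ptp(dw) <= 1e-8 * max(np.max(dw), 1e-300):
        # featureless (constant-slope) curve: no extremum to refine
        return TransitionDetection(temperature_K=float(tw[0]), boundary_warning=True)
    k = int(np.argmax(dw))
    if k == 0 or k == len(tw) - 1:
        return TransitionDetection(temperature_K=float(tw[k]), boundary_warning=True)
    a, b, _ = np.polyfit(tw[k - 1 : k + 2], dw[k - 1 : k + 2], 2)
    t_peak = float(-b / (2 * a)) if a != 0 else float(tw[k])
    if not (tw[k - 1] <= t_peak <= tw[k + 1]):
        t_peak = float(tw[k])
    return TransitionDetection(temperature_K=t_peak, boundary_warning=False)


def assemble_profile(records: list[ProxyRecord], sort_by_depth: bool = True) -> pd.DataFrame:
    """Join per-depth proxy records into a depth-ordered profile table.

    Derived columns (s_ratio, hirm, carbonate-free values) are computed
    where their inputs are present and left null otherwise.  Duplicate
    depths raise.
    """
    if not records:
        raise ValueError("no records")
    depths = [r.depth_mcd for r in records]
    if len(set(depths)) != len(depths):
        raise ValueError("duplicate depths in profile")
    rows = []
    for r in records:
        row: dict = {
            "depth_mcd": r.depth_mcd,
            "irm_1T": r.irm_1T,
            "irm_m0p3T": r.irm_m0p3T,
            "carbonate_fraction": r.carbonate_fraction,
            "ms": r.ms,
            "mrs_over_ms": r.mrs_over_ms,
            "bc_mT": r.bc_mT,
            "bcr_mT": r.bcr_mT,
            "biogenic_b_half_mT": r.biogenic_b_half_mT,
            "biogenic_dp": r.biogenic_dp,
            "biogenic_fraction": r.biogenic_fraction,
        }
        if r.irm_1T is not None and r.irm_m0p3T is not None:
            row["s_ratio"] = s_ratio(r.irm_1T, r.irm_m0p3T)
            row["hirm"] = hirm(r.irm_1T, r.irm_m0p3T)
        else:
            row["s_ratio"] = None
            row["hirm"] = None
        cf = r.carbonate_fraction
        row["hirm_cfb"] = (
            carbonate_free(row["hirm"], cf) if row["hirm"] is not None and cf is not None else None
        )
        row["ms_cfb"] = carbonate_free(r.ms, cf) if r.ms is not None and cf is not None else None
        rows.append(row)
    df = pd.DataFrame(rows)
    if sort_by_depth:
        df = df.sort_values("depth_mcd", ignore_index=True)
    return df
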
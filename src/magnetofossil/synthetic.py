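"""Synthetic inputs emulating the statistical structure of magnetofossil data.

Every downstream stage of the package (morphometry, chain building, FORC
simulation, IRM unmixing, down-core proxies) consumes one of four input
kinds that in a real study come from TEM measurements and magnetometry:

* crystal measurement tables — lengths close to log-normal, axial ratios
  (width/length) unimodal below 1, a small operator-labelled share of
  bullet-shaped crystals;
* IRM acquisition curves — sums of cumulative log-Gaussian coercivity
  components sampled at log-spaced fields;
* down-core proxy tables — depth-ordered records with smooth trends plus
  noise.

The generators here produce all of them deterministically from a seed, so
tests and examples never require measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .morphometry import CrystalMeasurement

__all__ = [
    "CrystalPopulationSpec",
    "IrmComponentSpec",
    "IrmCurve",
    "generate_crystal_population",
    "generate_irm_curve",
    "generate_downcore_table",
]


@dataclass(frozen=True)
class CrystalPopulationSpec:
    """Parameters of a synthetic magnetofossil crystal population.

    Lengths are drawn log-normally (log-normal length histograms are the
    norm for magnetofossil populations); axial ratios width/length are
    normal, clipped to (0, 1].  ``bullet_fraction`` of the crystals are
    labelled "bullet" by quota (``round(n × fraction)``) so small fixtures
    carry exact shares.
    """

    n_crystals: int
    length_logmean: float  # mean of ln(length/nm)
    length_logsd: float
    axial_ratio_mean: float
    axial_ratio_sd: float
    bullet_fraction: float = 0.0
    sample_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crystals < 1:
            raise ValueError("n_crystals must be >= 1")
        if self.length_logsd < 0:
            raise ValueError("length_logsd must be >= 0")
        if not (0 < self.axial_ratio_mean <= 1):
            raise ValueError("axial_ratio_mean must lie in (0, 1]")
        if self.axial_ratio_sd < 0:
            raise ValueError("axial_ratio_sd must be >= 0")
        if not (0 <= self.bullet_fraction <= 1):
            raise ValueError("bullet_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class IrmComponentSpec:
    """One cumulative log-Gaussian coercivity component.

    ``log_b_half`` is log10 of the median acquisition field B½ in mT and
    ``dp`` the dispersion parameter (standard deviation in log10 field).
    """

    amplitude: float
    log_b_half: float
    dp: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.dp <= 0:
            raise ValueError("dp must be > 0")

    def cdf(self, field_mT: np.ndarray) -> np.ndarray:
        """Component contribution A·Φ((log10 B − log10 B½)/DP)."""
        z = (np.log10(field_mT) - self.log_b_half) / self.dp
        return self.amplitude * norm.cdf(z)


@dataclass
class IrmCurve:
    """An IRM acquisition curve: remanence versus applied field."""

    fields_mT: np.ndarray
    remanence: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fields_mT = np.asarray(self.fields_mT, dtype=float)
        self.remanence = np.asarray(self.remanence, dtype=float)
        if self.fields_mT.size != self.remanence.size:
            raise ValueError("fields and remanence must have equal length")
        if self.fields_mT.size < 10:
            raise ValueError("IRM curve needs at least 10 points")
        if np.any(self.fields_mT <= 0) or np.any(np.diff(self.fields_mT) <= 0):
            raise ValueError("fields must be positive and strictly increasing")


def generate_crystal_population(spec: CrystalPopulationSpec) -> list[CrystalMeasurement]:
    """Draw a deterministic synthetic crystal population.

    Lengths ~ LogNormal(length_logmean, length_logsd) in nm; axial ratios ~
    Normal(mean, sd) clipped to (0, 1]; widths = length × ratio.  Exactly
    ``round(n × bullet_fraction)`` crystals are labelled bullet (quota
    sampling), the rest left unlabelled for downstream classification.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = rng.lognormal(spec.length_logmean, spec.length_logsd, spec.n_crystals)
    ratios = rng.normal(spec.axial_ratio_mean, spec.axial_ratio_sd, spec.n_crystals)
    ratios = np.clip(ratios, 1e-3, 1.0)
    widths = lengths * ratios

    n_bullet = int(round(spec.n_crystals * spec.bullet_fraction))
    bullet_idx = set(rng.choice(spec.n_crystals, size=n_bullet, replace=False).tolist())
    return [
        CrystalMeasurement(
            sample_id=spec.sample_id,
            length=float(lengths[i]),
            width=float(widths[i]),
            morphology="bullet" if i in bullet_idx else "unlabelled",
        )
        for i in range(spec.n_crystals)
    ]


def generate_irm_curve(
    components: list[IrmComponentSpec],
    n_points: int = 80,
    field_range: tuple[float, float] = (1.0, 1000.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> IrmCurve:
    """Synthesize an IRM acquisition curve from coercivity components.

    Fields are logarithmically spaced over ``field_range`` (mT), matching
    the 80-point log-spaced protocol of vibrating-sample magnetometer IRM
    acquisition.  Noise is multiplicative Gaussian with relative standard
    deviation ``noise_sd``; with ``noise_sd=0`` the curve is exactly the
    component sum and hence non-decreasing.
    """
    if not components:
        raise ValueError("need at least one IRM component")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    lo, hi = field_range
    if lo <= 0 or hi <= lo:
        raise ValueError("field_range must be positive and increasing")
    fields = np.logspace(np.log10(lo), np.log10(hi), n_points)
    curve = np.zeros_like(fields)
    for comp in components:
        curve += comp.cdf(fields)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve = curve * (1.0 + noise_sd * rng.standard_normal(n_points))
    meta = {"seed": seed, "noise_sd": noise_sd, "n_components": len(components)}
    return IrmCurve(fields, curve, sample_id=sample_id, metadata=meta)


def generate_downcore_table(
    n_depths: int,
    trend_spec: dict[str, tuple[float, float, float]],
    depth_range: tuple[float, float] = (335.0, 336.0),
    seed: int = 0,
):
    """Generate a depth-ordered down-core table with linear trends + noise.

    ``trend_spec`` maps column name → (intercept, slope per metre, noise sd).
    Depths are evenly spaced over ``depth_range`` (metres composite depth).
    Returns a pandas DataFrame with a ``depth_mcd`` column.
    """
    import pandas as pd

    if n_depths < 2:
        raise ValueError("n_depths must be >= 2")
    rng = np.random.default_rng(seed)
    depths = np.linspace(depth_range[0], depth_range[1], n_depths)
    data = {"depth_mcd": depths}
    for name, (intercept, slope, noise) in trend_spec.items():
        col = intercept + slope * (depths - depths[0])
        if noise > 0:
            col = col + noise * rng.standard_normal(n_depths)
        data[name] = col
    return pd.DataFrame(data)
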
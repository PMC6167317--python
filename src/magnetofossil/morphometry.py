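"""Morphometry of magnetofossil crystal populations.

TEM-derived crystal measurements (length, width, optional operator
morphology label) are summarized the way magnetofossil studies present
them: three morphology groups (isotropic/nearly isotropic cubo-octahedra,
elongated crystals and prisms, bullet-shaped crystals), length and axial
ratio histograms and Tukey box-whisker statistics computed excluding
bullets, and two-sample Kolmogorov–Smirnov comparisons of length
distributions between samples.

Bullet-shaped crystals are operator-identified: bullet shape cannot be
recovered from the two measured axes alone, so a pre-assigned "bullet"
label always takes precedence over the geometric cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import kolmogorov

__all__ = [
    "CrystalMeasurement",
    "MorphometrySummary",
    "KsResult",
    "classify_morphology",
    "bullet_fraction",
    "ks_two_sample",
    "summarize",
]

MORPHOLOGIES = ("isotropic", "elongated", "bullet", "unlabelled")


@dataclass
class CrystalMeasurement:
    """A single measured crystal: length ≥ width > 0, both in nm."""

    sample_id: str
    length: float
    width: float
    morphology: str = "unlabelled"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("length and width must be positive")
        if self.width > self.length:
            raise ValueError(
                f"width ({self.width}) exceeds length ({self.length}); "
                "axial ratio is defined as width/length <= 1"
            )
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")

    @property
    def axial_ratio(self) -> float:
        return self.width / self.length


@dataclass
class BoxStats:
    """Tukey box-whisker statistics of one variable."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float
    sd: float


@dataclass
class MorphometrySummary:
    n_total: int
    n_bullet: int
    bullet_percent: float
    length_stats: BoxStats
    axial_ratio_stats: BoxStats
    length_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    axial_ratio_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


@dataclass
class KsResult:
    d_statistic: float
    p_value: float
    n1: int
    n2: int


def classify_morphology(
    crystals: list[CrystalMeasurement],
    axial_ratio_cutoff: float = 0.9,
    auto_swap: bool = False,
) -> list[CrystalMeasurement]:
    """Assign the three morphology groups.

    Crystals already labelled "bullet" keep that label.  All others are
    classed isotropic when axial ratio ≥ cutoff and elongated otherwise.
    The default cutoff of 0.9 separates near-equant cubo-octahedra from
    elongated prisms; there is no universal community value, so it is
    configurable.

    With ``auto_swap`` a measurement with width > length has its axes
    exchanged instead of raising.
    """
    if not (0 < axial_ratio_cutoff < 1):
        raise ValueError("axial_ratio_cutoff must lie in (0, 1)")
    out = []
    for c in crystals:
        length, width = c.length, c.width
        if width > length:
            if not auto_swap:
                raise ValueError("width > length; enable auto_swap to exchange axes")
            length, width = width, length
        if c.morphology == "bullet":
            label = "bullet"
        elif width / length >= axial_ratio_cutoff:
            label = "isotropic"
        else:
            label = "elongated"
        out.append(CrystalMeasurement(c.sample_id, length, width, label))
    return out


def bullet_fraction(crystals: list[CrystalMeasurement]) -> float:
    """Percentage of bullet-labelled crystals (0–100)."""
    if not crystals:
        raise ValueError("empty crystal collection")
    n_bullet = sum(1 for c in crystals if c.morphology == "bullet")
    return 100.0 * n_bullet / len(crystals)


def ks_two_sample(x, y) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum of |F̂x − F̂y| over the pooled support; the p-value
    uses the asymptotic Kolmogorov distribution with effective sample size
    n1·n2/(n1+n2).  For the moderate-to-large crystal counts involved the
    asymptotic p is adequate; exact small-sample p-values are deliberately
    not computed.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = n1 * n2 / (n1 + n2)
    p = float(kolmogorov(np.sqrt(en) * d))
    return KsResult(d_statistic=d, p_value=min(1.0, p), n1=n1, n2=n2)


def _box_stats(values: np.ndarray) -> BoxStats:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
    )


def _hist(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    # degenerate (constant) samples cannot support multiple finite bins
    if np.ptp(values) <= 1e-12 * max(1.0, float(np.abs(values).max())):
        return np.histogram(values, bins=1)
    return np.histogram(values, bins=n_bins)


def summarize(
    crystals: list[CrystalMeasurement],
    exclude_bullets: bool = True,
    n_bins: int = 20,
) -> MorphometrySummary:
    """Box-whisker statistics and histograms of length and axial ratio.

    Bullet-shaped crystals are excluded by default, matching the convention
    of reporting size statistics for the cubo-octahedral + prismatic
    population only.  Quartiles use linear interpolation; whiskers are the
    most extreme observations within 1.5×IQR of the quartiles (Tukey).
    """
    if not crystals:
        raise ValueError("empty crystal collection")
    n_total = len(crystals)
    n_bullet = sum(1 for c in crystals if c.morphology == "bullet")
    kept = [c for c in crystals if not (exclude_bullets and c.morphology == "bullet")]
    if not kept:
        raise ValueError("no crystals remain after bullet exclusion")
    lengths = np.array([c.length for c in kept])
    ratios = np.array([c.axial_ratio for c in kept])
    return MorphometrySummary(
        n_total=n_total,
        n_bullet=n_bullet,
        bullet_percent=100.0 * n_bullet / n_total,
        length_stats=_box_stats(lengths),
        axial_ratio_stats=_box_stats(ratios),
        length_hist=_hist(lengths, n_bins),
        axial_ratio_hist=_hist(ratios, n_bins),
    )
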
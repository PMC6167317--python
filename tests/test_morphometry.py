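"""Crystal morphometry: classification, KS test, box-whisker summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from magnetofossil.morphometry import (
    CrystalMeasurement,
    bullet_fraction,
    classify_morphology,
    ks_two_sample,
    summarize,
)


def _c(length, width, morph="unlabelled"):
    return CrystalMeasurement("s", length, width, morph)


def brute_force_ks_d(x, y):
    """sup |Fx - Fy| over every pooled threshold, by direct counting."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestClassify:
    def test_examples(self):
        iso, elong, bullet = classify_morphology(
            [_c(50, 50), _c(100, 60), _c(100, 95, "bullet")], axial_ratio_cutoff=0.9
        )
        assert iso.morphology == "isotropic"
        assert elong.morphology == "elongated"
        assert bullet.morphology == "bullet"  # operator label has precedence

    def test_partition_sums_to_total(self, synthetic_population):
        labelled = classify_morphology(synthetic_population)
        counts = {m: sum(1 for c in labelled if c.morphology == m) for m in
                  ("isotropic", "elongated", "bullet")}
        assert sum(counts.values()) == len(synthetic_population)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            classify_morphology([_c(50, 50)], axial_ratio_cutoff=1.5)

    def test_width_exceeding_length_is_rejected_by_type(self):
        with pytest.raises(ValueError):
            _c(50, 60)


class TestBulletFraction:
    @pytest.mark.parametrize(
        "n_bullet,n_total,expected", [(2, 250, 0.8), (0, 50, 0.0), (4, 100, 4.0)]
    )
    def test_percentages(self, n_bullet, n_total, expected):
        crystals = [_c(60, 50, "bullet")] * n_bullet + [_c(60, 50)] * (n_total - n_bullet)
        assert bullet_fraction(crystals) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bullet_fraction([])


class TestKs:
    def test_identical_samples_give_zero(self):
        r = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert r.d_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_one(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).d_statistic == 1.0

    def test_interleaved_quarter(self):
        assert ks_two_sample([1, 3, 5, 7], [2, 4, 6, 8]).d_statistic == pytest.approx(0.25)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=25),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=25),
    )
    def test_d_matches_brute_force(self, x, y):
        assert ks_two_sample(x, y).d_statistic == pytest.approx(brute_force_ks_d(x, y))

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.4, 1.2, 60)
        ours = ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y, method="asymp")
        assert ours.d_statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.2)

    def test_p_monotone_in_d(self):
        from scipy.special import kolmogorov

        en = np.sqrt(40 * 40 / 80)
        ds = np.linspace(0.05, 0.9, 30)
        ps = kolmogorov(en * ds)
        assert np.all(np.diff(ps) < 0)


class TestSummarize:
    def test_median_simple(self):
        s = summarize([_c(10, 8), _c(20, 16), _c(30, 24)])
        assert s.length_stats.median == 20

    def test_quartiles_linear_interpolation(self):
        crystals = [_c(float(v), float(v) * 0.8) for v in range(1, 9)]
        s = summarize(crystals)
        assert s.length_stats.q1 == pytest.approx(2.75)
        assert s.length_stats.q3 == pytest.approx(6.25)

    def test_all_bullets_excluded_errors(self):
        with pytest.raises(ValueError):
            summarize([_c(60, 50, "bullet")], exclude_bullets=True)

    def test_order_invariance(self, synthetic_population):
        rng = np.random.default_rng(5)
        shuffled = list(synthetic_population)
        rng.shuffle(shuffled)
        a = summarize(synthetic_population)
        b = summarize(shuffled)
        for field in ("median", "q1", "q3", "whisker_low", "whisker_high", "mean", "sd"):
            assert getattr(a.length_stats, field) == pytest.approx(
                getattr(b.length_stats, field), rel=1e-12
            )
            assert getattr(a.axial_ratio_stats, field) == pytest.approx(
                getattr(b.axial_ratio_stats, field), rel=1e-12
            )

    def test_tukey_whiskers_within_fences(self):
        vals = [10.0] * 20 + [100.0]  # one far outlier
        crystals = [_c(v, v * 0.8) for v in vals]
        s = summarize(crystals)
        assert s.length_stats.whisker_high == 10.0  # outlier excluded
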
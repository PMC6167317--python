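"""FORC processing: mixed-derivative estimation, ridge and backfield profiles."""

import numpy as np
import pytest

from magnetofossil.assemblage import oriented_ensemble
from magnetofossil.forcproc import (
    VariforcParams,
    compute_forc_distribution,
    extract_backfield_profile,
    extract_central_ridge,
)
from magnetofossil.micromag import FieldProtocol, ForcDataset, run_forc


def make_surface(func, delta=2.0, span=30.0):
    ba = np.arange(span, -span - delta / 2, -delta)
    bb = np.arange(-span, span + delta / 2, delta)
    m = np.where(bb[None, :] >= ba[:, None] - 1e-9, func(ba[:, None], bb[None, :]), np.nan)
    return ForcDataset(ba=ba, bb=bb, magnetization=m)


def _interior_mask(dist, ds, margin):
    """Grid points whose smoothing windows cannot touch a data boundary."""
    gu, gc = np.meshgrid(dist.bu, dist.bc, indexing="ij")
    ba_pt = gu - gc
    bb_pt = gu + gc
    pad = margin * ds.field_step
    return (
        (ba_pt > ds.ba.min() + pad)
        & (ba_pt < ds.ba.max() - pad)
        & (bb_pt < ds.bb.max() - pad)
        & (gc > pad / 2)
    )


class TestDistribution:
    def test_bilinear_surface_gives_constant_rho(self):
        ds = make_surface(lambda a, b: a * b)
        dist = compute_forc_distribution(ds)
        interior = dist.rho[3:-3, 3:-3]
        assert np.nanmax(np.abs(interior + 0.5)) < 1e-6

    def test_ba_independent_quadratic_surface_gives_exact_zero(self):
        ds = make_surface(lambda a, b: 0.3 * b + 0.01 * b * b + 0 * a, span=50.0)
        dist = compute_forc_distribution(ds)
        inner = _interior_mask(dist, ds, margin=10)
        assert np.nanmax(np.abs(dist.rho[inner])) < 1e-9

    def test_ba_independent_smooth_surface_bias_is_small(self):
        # the rotated (ridge-preserving) windows couple the mixed term
        # weakly to cubic pure-Bb structure; the residual bias must stay
        # far below the signal scale of a comparable genuine distribution
        ds = make_surface(lambda a, b: np.tanh(b / 10.0) + 0 * a, span=50.0)
        dist = compute_forc_distribution(ds)
        inner = _interior_mask(dist, ds, margin=10)
        assert np.nanmax(np.abs(dist.rho[inner])) < 1e-3

    def test_noisy_constant_derivative_unbiased(self):
        rng = np.random.default_rng(0)
        ds = make_surface(lambda a, b: a * b)
        noise = 0.01 * rng.standard_normal(ds.magnetization.shape)
        ds.magnetization = ds.magnetization + noise
        dist = compute_forc_distribution(ds)
        interior = dist.rho[4:-4, 4:-4]
        vals = interior[~np.isnan(interior)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # windows overlap, so neighbouring estimates correlate; allow for
        # the effective-sample-size reduction with a conservative factor
        assert abs(vals.mean() + 0.5) < max(3 * se * 5, 0.01)

    def test_scaling_commutes(self):
        ds = make_surface(lambda a, b: a * b + 0.3 * b**2)
        d1 = compute_forc_distribution(ds)
        ds2 = ForcDataset(ds.ba, ds.bb, 3.0 * ds.magnetization)
        d2 = compute_forc_distribution(ds2)
        assert np.allclose(d2.rho, 3.0 * d1.rho, equal_nan=True, atol=1e-9)

    def test_more_smoothing_never_raises_max(self):
        rng = np.random.default_rng(1)
        ds = make_surface(lambda a, b: a * b / 100.0)
        ds.magnetization = ds.magnetization + 0.05 * rng.standard_normal(ds.magnetization.shape)
        small = compute_forc_distribution(ds, VariforcParams(2, 2, 2, 2, 0.0, 0.0))
        large = compute_forc_distribution(ds, VariforcParams(6, 6, 6, 6, 0.0, 0.0))
        assert np.nanmax(np.abs(large.rho)) <= np.nanmax(np.abs(small.rho)) + 1e-12

    def test_irregular_grid_rejected(self):
        ba = np.array([10.0, 7.0, 5.0, 2.0, 0.0, -3.0])
        bb = np.arange(-10.0, 11.0, 2.0)
        m = np.ones((ba.size, bb.size))
        with pytest.raises(ValueError, match="regrid"):
            compute_forc_distribution(ForcDataset(ba, bb, m))

    def test_smoothing_validation(self):
        with pytest.raises(ValueError):
            VariforcParams(sc0=0.5)


class TestCentralRidge:
    def test_zero_distribution_gives_zero_profile(self):
        from magnetofossil.forcproc import ForcDistribution, VariforcParams

        dist = ForcDistribution(
            bc=np.arange(0.0, 20.0, 2.0),
            bu=np.arange(-10.0, 11.0, 2.0),
            rho=np.zeros((11, 10)),
            params=VariforcParams(),
        )
        prof = extract_central_ridge(dist, bu_halfwidth=2 * dist.bu_step)
        assert np.allclose(prof.density, 0.0)
        assert prof.ridge_fraction == 0.0

    def test_halfwidth_below_resolution_rejected(self):
        ds = make_surface(lambda a, b: a * b)
        dist = compute_forc_distribution(ds)
        with pytest.raises(ValueError):
            extract_central_ridge(dist, bu_halfwidth=0.1 * dist.bu_step)


class TestBackfield:
    def test_identical_aligned_particles_peak_at_switching_field(self):
        """Isolated particles with a common switching field B* produce a
        backfield profile peaking at B* within one field step."""
        axes = np.tile([0.0, 0.0, 1.0], (60, 1))
        asm = oriented_ensemble(60.0, 40.0, axes)
        bstar = asm.b_sw[0]
        prot = FieldProtocol(kind="forc", n_forcs=40, bc_max=120, bu_max=40)
        ds = run_forc(asm, prot, n_realizations=1, seed=0, interactions=False, bb_max=0.0)
        prof = extract_backfield_profile(ds)
        peak = prof.field_mT[np.argmax(prof.density)]
        assert abs(peak - bstar) <= ds.field_step
        assert prof.bcr_mT == pytest.approx(bstar, abs=ds.field_step)

    def test_saturated_reversible_dataset_is_flat(self):
        ds = make_surface(lambda a, b: np.ones_like(a + b))
        prof = extract_backfield_profile(ds)
        assert np.allclose(prof.density, 0.0, atol=1e-12)
        assert prof.bcr_mT is None

    def test_missing_zero_column_rejected(self):
        ba = np.arange(12.0, 1.0, -2.0)
        bb = np.arange(2.0, 13.0, 2.0)
        m = np.ones((ba.size, bb.size))
        with pytest.raises(ValueError, match="Bb"):
            extract_backfield_profile(ForcDataset(ba, bb, m))
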
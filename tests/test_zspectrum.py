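"""Voxel-wise processing chain: segmentation, spline fits, B0 correction,
asymmetry ST and quality filtering."""

import math

import numpy as np
import pytest

import glucocest as gc
from glucocest.containers import ZSpectrum
from glucocest.zspectrum import ProcessingConfig


class TestSegmentForeground:
    def test_all_zero_image_warns_and_is_empty(self):
        stack = gc.ZSpectrumStack(np.zeros((8, 8, 21)), np.linspace(10, -10, 21))
        with pytest.warns(UserWarning, match="empty"):
            mask = gc.segment_foreground(stack)
        assert not mask.any()

    def test_uniform_positive_image_is_full(self):
        stack = gc.ZSpectrumStack(np.ones((8, 8, 21)), np.linspace(10, -10, 21))
        assert gc.segment_foreground(stack).all()

    def test_vial_overlap_with_truth_labels(self, invitro_acq, sat3):
        ph = gc.generate_phantom(gc.glucose(), acq=invitro_acq, sat=sat3, snr=50, seed=4)
        mask = gc.segment_foreground(ph.stack)
        truth = ph.labels > 0
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.95

    def test_threshold_fraction_validated(self, noisefree_phantom):
        with pytest.raises(ValueError):
            gc.segment_foreground(noisefree_phantom.stack, threshold_fraction=1.5)


class TestFitVoxel:
    def test_noise_free_spectrum_fits_nearly_perfectly(self, glucose_spectrum):
        fit = gc.fit_voxel(glucose_spectrum.offsets, glucose_spectrum.signals)
        assert fit.valid
        assert fit.r2 >= 0.999
        # strong asymmetric CEST on a saturated flat bottom: the centring
        # convention carries a small documented downfield bias
        assert abs(fit.water_center) <= 0.02

    def test_water_center_exact_on_invivo_lineshape(self, invivo_acq):
        # weak-CEST tissue spectrum: the water centre is well conditioned
        spec = gc.simulate_zspectrum(
            gc.glucose(), 0.0, 7.0, gc.water_preset(7.0, "tissue"),
            gc.SaturationScheme(2.0, 5.0), invivo_acq,
        )
        fit = gc.fit_voxel(spec.offsets, spec.signals)
        assert fit.r2 >= 0.999
        assert abs(fit.water_center) <= 0.01

    def test_pure_noise_rarely_passes_the_r2_filter(self):
        rng = np.random.default_rng(11)
        x = np.linspace(-10, 10, 61)
        n_pass = 0
        for _ in range(100):
            y = np.clip(0.5 + rng.normal(0, 0.02, 61), 0, None)
            fit = gc.fit_voxel(x, y)
            n_pass += fit.r2 > 0.97
        assert n_pass <= 5

    def test_interpolation_limit_passes_through_samples(self, glucose_spectrum):
        fit = gc.fit_voxel(glucose_spectrum.offsets, glucose_spectrum.signals, smoothing=0.0)
        asc = glucose_spectrum.ascending
        assert np.max(np.abs(fit.spline(asc.offsets) - asc.signals)) < 1e-9

    def test_constant_signal_is_invalid_with_zero_r2(self):
        fit = gc.fit_voxel(np.linspace(-10, 10, 21), np.ones(21))
        assert not fit.valid and fit.r2 == 0.0

    def test_nan_signal_is_invalid(self):
        y = np.ones(21)
        y[3] = np.nan
        fit = gc.fit_voxel(np.linspace(-10, 10, 21), y)
        assert not fit.valid

    def test_too_few_offsets_raise(self):
        with pytest.raises(ValueError, match="15"):
            gc.fit_voxel(np.linspace(-5, 5, 10), np.ones(10))


class TestCorrectB0:
    def test_centered_spectrum_resamples_to_identity(self):
        x = np.linspace(-10, 10, 201)
        y = 1 - 0.9 * np.exp(-(x**2) / 0.5)
        fit = gc.fit_voxel(x, y, smoothing=0.0)
        cor = gc.correct_b0(fit, x)
        assert abs(fit.water_center) < 0.006
        assert np.nanmax(np.abs(cor.signals - y)) < 1e-6

    def test_known_shift_is_recovered_and_recentred(self, noisefree_phantom):
        ph = noisefree_phantom
        shifted, _ = gc.add_b0_field(ph.stack, np.full(ph.stack.shape, 0.3))
        r, c = np.argwhere(ph.labels == 1)[0]
        spec = shifted.voxel(r, c)
        fit = gc.fit_voxel(spec.offsets, spec.signals)
        assert fit.water_center == pytest.approx(0.3, abs=0.02)
        cor = gc.correct_b0(fit, spec.offsets)
        asc = cor.ascending
        sel = np.abs(asc.offsets) <= 1.5
        assert abs(asc.offsets[sel][np.nanargmin(asc.signals[sel])]) <= 0.11

    def test_shift_beyond_window_raises(self):
        x = np.linspace(-10, 10, 201)
        y = 1 - 0.9 * np.exp(-((x - 2.0) ** 2) / 0.5)
        fit = gc.fit_voxel(x, y, smoothing=0.0, max_shift_ppm=3.0)
        with pytest.raises(ValueError, match="beyond"):
            gc.correct_b0(fit, x, max_shift_ppm=1.5)

    def test_invalid_fit_rejected(self):
        fit = gc.fit_voxel(np.linspace(-10, 10, 21), np.ones(21))
        with pytest.raises(ValueError, match="invalid"):
            gc.correct_b0(fit, np.linspace(-10, 10, 21))


class TestComputeSt:
    def test_direct_formula(self):
        spec = ZSpectrum(np.array([-10.0, -1.2, 1.2]), np.array([1.0, 0.8, 0.7]))
        assert gc.compute_st(spec, 1.2, s0=1.0) == pytest.approx(0.1)

    def test_symmetric_spectrum_gives_zero(self):
        x = np.linspace(-10, 10, 201)
        spec = ZSpectrum(x, 1 - 0.9 * np.exp(-(x**2)))
        assert gc.compute_st(spec, 1.2, s0=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_scaling_signals_and_s0_leaves_st_unchanged(self):
        x = np.linspace(-10, 10, 201)
        y = 1 - 0.9 * np.exp(-(x**2)) - 0.05 * np.exp(-((x - 1.2) ** 2))
        a = gc.compute_st(ZSpectrum(x, y), 1.2, s0=1.0)
        b = gc.compute_st(ZSpectrum(x, 3.7 * y), 1.2, s0=3.7)
        assert b == pytest.approx(a, rel=1e-12)

    def test_invalid_s0_or_missing_support(self):
        spec = ZSpectrum(np.array([-10.0, -1.2, 1.2]), np.array([1.0, 0.8, 0.7]))
        assert math.isnan(gc.compute_st(spec, 1.2, s0=0.0))
        assert math.isnan(gc.compute_st(spec, 2.0, s0=1.0))


class TestFilterQuality:
    def test_perfect_fits_pass_everywhere(self):
        m = gc.filter_quality(np.ones((4, 4)), np.ones((4, 4), bool))
        assert m.all()

    def test_threshold_is_strict(self):
        r2 = np.full((4, 4), 0.97)
        assert not gc.filter_quality(r2, np.ones((4, 4), bool)).any()

    def test_mixed_grid_matches_brute_force(self):
        rng = np.random.default_rng(0)
        r2 = rng.uniform(0.9, 1.0, (16, 16))
        valid = rng.random((16, 16)) > 0.2
        fg = rng.random((16, 16)) > 0.3
        m = gc.filter_quality(r2, valid, fg, 0.97)
        expect = sum(
            1
            for i in range(16)
            for j in range(16)
            if r2[i, j] > 0.97 and valid[i, j] and fg[i, j]
        )
        assert m.sum() == expect

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(1)
        r2 = rng.uniform(0.9, 1.0, (12, 12))
        valid = np.ones((12, 12), bool)
        lo = gc.filter_quality(r2, valid, r2_threshold=0.95)
        hi = gc.filter_quality(r2, valid, r2_threshold=0.99)
        assert not (hi & ~lo).any()


class TestStMap:
    def test_noise_free_phantom_matches_truth(self, noisefree_phantom, noisefree_phantom_map):
        ph, res = noisefree_phantom, noisefree_phantom_map
        for vid in ph.pH_by_vial:
            sel = (ph.labels == vid) & res.mask
            assert sel.any()
            assert res.values[sel].mean() == pytest.approx(ph.truth_st[vid][1.2], abs=1e-3)

    def test_fieldmap_correction_restores_st(self, noisefree_phantom, noisefree_phantom_map):
        ph = noisefree_phantom
        shifted, _ = gc.add_b0_field(ph.stack, np.full(ph.stack.shape, 0.3))
        res = gc.st_map(shifted)
        ref = noisefree_phantom_map
        for vid in ph.pH_by_vial:
            sel = (ph.labels == vid) & res.mask & ref.mask
            dev = abs(res.values[sel].mean() - ref.values[sel].mean())
            assert dev < 0.01

    def test_empty_foreground_yields_all_masked_map(self):
        stack = gc.ZSpectrumStack(np.zeros((8, 8, 21)), np.linspace(10, -10, 21))
        with pytest.warns(UserWarning):
            res = gc.st_map(stack)
        assert not res.mask.any()
        assert np.all(np.isnan(res.values))

    def test_unmasked_voxels_are_finite(self, noisefree_phantom_map):
        res = noisefree_phantom_map
        assert np.all(np.isfinite(res.values[res.mask]))
        assert np.all(np.isnan(res.values[~res.mask]))

    def test_phantom_ph_ordering_survives_processing(self, noisefree_phantom, noisefree_phantom_map):
        ph, res = noisefree_phantom, noisefree_phantom_map
        by_ph = {
            ph.pH_by_vial[v]: res.values[(ph.labels == v) & res.mask].mean()
            for v in ph.pH_by_vial
        }
        assert by_ph[6.0] > by_ph[7.4] and by_ph[6.2] > by_ph[7.4]
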
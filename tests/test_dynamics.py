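"""Delta-ST maps, enhanced fractions, time courses and group statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import glucocest as gc
from glucocest.zspectrum import STMap


def _stmap(values, mask=None, offset=1.2):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    return STMap(values, np.asarray(mask, bool), offset)


class TestDeltaSt:
    def test_identical_maps_give_zero(self):
        a = _stmap(np.full((4, 4), 0.02))
        dm = gc.delta_st(a, a)
        assert np.allclose(dm.values[dm.mask], 0.0)

    def test_formula_in_percentage_points(self):
        pre = _stmap(np.full((2, 2), 0.01))
        post = _stmap(np.full((2, 2), 0.03))
        dm = gc.delta_st(pre, post)
        assert np.allclose(dm.values[dm.mask], 2.0)

    def test_voxelwise_additivity(self):
        rng = np.random.default_rng(0)
        a, b, c = (_stmap(rng.normal(0.02, 0.01, (5, 5))) for _ in range(3))
        ab = gc.delta_st(a, b).values
        bc = gc.delta_st(b, c).values
        ac = gc.delta_st(a, c).values
        assert np.allclose(ab + bc, ac)

    def test_mask_is_intersection(self):
        pre = _stmap(np.ones((3, 3)), mask=np.tri(3, dtype=bool))
        post = _stmap(np.ones((3, 3)), mask=np.tri(3, dtype=bool).T)
        dm = gc.delta_st(pre, post)
        assert dm.mask.sum() == 3  # diagonal only

    def test_geometry_and_offset_mismatch_raise(self):
        with pytest.raises(ValueError, match="geometry"):
            gc.delta_st(_stmap(np.ones((2, 2))), _stmap(np.ones((3, 3))))
        with pytest.raises(ValueError, match="offsets differ"):
            gc.delta_st(_stmap(np.ones((2, 2)), offset=0.8), _stmap(np.ones((2, 2))))


class TestEnhancedFraction:
    def test_all_positive_and_all_negative(self):
        roi = np.ones((4, 4), bool)
        up = gc.DeltaSTMap(np.ones((4, 4)), roi)
        down = gc.DeltaSTMap(-np.ones((4, 4)), roi)
        assert gc.enhanced_fraction(up, roi) == 100.0
        assert gc.enhanced_fraction(down, roi) == 0.0

    def test_zero_mean_noise_is_near_half(self):
        rng = np.random.default_rng(7)
        roi = np.ones((40, 25), bool)  # 1000 roi voxels per draw
        fracs = [
            gc.enhanced_fraction(gc.DeltaSTMap(rng.normal(0, 1, roi.shape), roi), roi)
            for _ in range(10)
        ]
        # each draw is Binomial(1000, 1/2): individual draws stay in 50 +/- 5
        # almost always, and the mean pins it down well inside the band
        assert abs(np.mean(fracs) - 50.0) <= 2.5

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (10, 10))
        roi = np.ones((10, 10), bool)
        a = gc.enhanced_fraction(gc.DeltaSTMap(vals, roi), roi)
        b = gc.enhanced_fraction(gc.DeltaSTMap(vals * 17.3, roi), roi)
        assert a == b

    def test_empty_intersection_is_nan_not_zero(self):
        dm = gc.DeltaSTMap(np.ones((4, 4)), np.zeros((4, 4), bool))
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(gc.enhanced_fraction(dm, np.ones((4, 4), bool)))


class TestRoiTimeCourse:
    def test_single_frame_single_row(self):
        dm = gc.DeltaSTMap(np.ones((4, 4)), np.ones((4, 4), bool), frame_time=6.0)
        tc = gc.roi_time_course([dm], np.ones((4, 4), bool))
        assert len(tc) == 1
        assert tc.loc[0, "frame_time_min"] == 6.0
        assert tc.loc[0, "mean_dst_pct"] == pytest.approx(1.0)

    def test_frames_keep_order_and_stats(self):
        rng = np.random.default_rng(1)
        roi = np.ones((6, 6), bool)
        maps = [
            gc.DeltaSTMap(rng.normal(m, 0.1, (6, 6)), roi, frame_time=t)
            for m, t in [(1.0, 6.0), (2.0, 12.0)]
        ]
        tc = gc.roi_time_course(maps, roi)
        assert list(tc["frame_time_min"]) == [6.0, 12.0]
        assert tc["mean_dst_pct"].iloc[1] > tc["mean_dst_pct"].iloc[0]
        assert (tc["enhanced_fraction_pct"] >= 0).all()


class TestAnovaDunnett:
    def test_identical_constants_are_flagged_degenerate(self):
        res = gc.anova_dunnett(np.full((5, 4), 2.0))
        assert res.degenerate
        assert not res.significant.any()

    def test_two_groups_match_two_sample_t_test(self):
        # with a single comparison Dunnett reduces to the two-sided t test
        rng = np.random.default_rng(2)
        data = np.column_stack([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        res = gc.anova_dunnett(data, baseline_frame=0)
        t = sps.ttest_ind(data[:, 1], data[:, 0])
        assert res.dunnett_pvalues[0] == pytest.approx(t.pvalue, abs=2e-3)

    def test_large_shift_is_detected_with_high_power(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            data = rng.normal(0, 1, (5, 5))
            data[:, -1] += 3.0  # last frame mean +3 sd
            res = gc.anova_dunnett(data, baseline_frame=0)
            hits += bool(res.significant[-1])
        assert hits / 50 > 0.9

    def test_familywise_error_is_calibrated(self):
        # null: all frames share one mean; reject if any Dunnett comparison hits
        rng = np.random.default_rng(4)
        n_rep, fw = 400, 0
        for _ in range(n_rep):
            res = gc.anova_dunnett(rng.normal(0, 1, (5, 5)), baseline_frame=0)
            fw += bool(res.significant.any())
        assert 0.02 <= fw / n_rep <= 0.08  # nominal 0.05, binomial slack

    def test_dataframe_input_pivots_by_frame_time(self):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(5)
        for s in range(4):
            for t in (6.0, 12.0, 18.0):
                rows.append(
                    {"subject": f"s{s}", "frame_time_min": t,
                     "mean_dst_pct": rng.normal(t / 6, 0.1)}
                )
        res = gc.anova_dunnett(pd.DataFrame(rows), baseline_frame=0)
        assert res.frame_labels == [6.0, 12.0, 18.0]
        assert res.reference_label == 6.0
        assert res.significant.all()

    def test_degenerate_shapes_raise(self):
        with pytest.raises(ValueError):
            gc.anova_dunnett(np.ones((1, 4)))
        with pytest.raises(ValueError):
            gc.anova_dunnett(np.ones((5, 1)))
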
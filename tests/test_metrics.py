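"""Image-quality metrics and semiquantitative ROI measures."""

import math

import numpy as np
import pytest

from petrestore import (CircularROI, PETVolume, bland_altman, corr2d_mean,
                        delta_suv, lbr, psnr, roi_stats, ssim, threshold_mask)


class TestPsnr:
    def test_uniform_difference_closed_form(self):
        x = np.ones((4, 4, 2))
        assert psnr(x, x + 0.1) == pytest.approx(20.0)   # V=1, MSE=0.01

    def test_identical_inputs_flagged_infinite(self, rng):
        x = rng.random((4, 4, 2))
        assert psnr(x, x) == math.inf

    def test_peak_is_evaluated_image_max(self, rng):
        x = rng.random((5, 5, 2)) * 3
        r = rng.random((5, 5, 2))
        mse = np.mean((x - r) ** 2)
        expected = 10 * math.log10(x.max() ** 2 / mse)
        assert psnr(x, r) == pytest.approx(expected)
        expected_ref = 10 * math.log10(r.max() ** 2 / mse)
        assert psnr(x, r, peak="reference") == pytest.approx(expected_ref)


class TestSsim:
    def test_equal_nonconstant_close_to_one(self, rng):
        x = rng.random((6, 6, 3))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_identical_constants_equal_one(self):
        c = np.full((4, 4, 2), 0.3)
        assert ssim(c, c) == pytest.approx(1.0)

    def test_matches_moment_oracle(self, rng):
        x, r = rng.random((5, 5, 4)), rng.random((5, 5, 4))
        mx, mr = x.mean(), r.mean()
        vx, vr = x.var(), r.var()
        cov = np.mean((x - mx) * (r - mr))
        a1, a2 = 1e-6, 3e-6
        expected = ((2 * mx * mr + a1) * (2 * cov + a2)
                    / ((mx ** 2 + mr ** 2 + a1) * (vx + vr + a2)))
        assert ssim(x, r) == pytest.approx(expected, rel=1e-12)

    def test_bounded(self, rng):
        x, r = rng.random((6, 6, 2)), rng.random((6, 6, 2))
        assert -1.0 <= ssim(x, r) <= 1.0

    def test_per_slice_option_averages_slice_values(self, rng):
        x, r = rng.random((6, 6, 3)), rng.random((6, 6, 3))
        expected = np.mean([ssim(x[:, :, d], r[:, :, d]) for d in range(3)])
        assert ssim(x, r, per_slice=True) == pytest.approx(expected)

    def test_windowed_variant_near_one_for_identical(self, rng):
        from petrestore.metrics import ssim_windowed
        x = rng.random((16, 16, 8))
        assert ssim_windowed(x, x) == pytest.approx(1.0, abs=1e-9)


class TestCorr2dMean:
    def test_identity_gives_one(self, rng):
        x = rng.random((5, 5, 3))
        assert corr2d_mean(x, x) == pytest.approx(1.0)

    def test_negated_gives_minus_one(self, rng):
        x = rng.random((5, 5, 3))
        assert corr2d_mean(x, -x + 2.0) == pytest.approx(-1.0)

    def test_constant_slices_skipped_and_counted(self, rng):
        x = rng.random((4, 4, 3))
        r = x.copy()
        x[:, :, 1] = 0.5
        r[:, :, 1] = 0.5
        val, skipped = corr2d_mean(x, r, return_skipped=True)
        assert skipped == 1
        assert val == pytest.approx(1.0)

    def test_all_degenerate_rejected(self):
        c = np.full((3, 3, 2), 1.0)
        with pytest.raises(ValueError):
            corr2d_mean(c, c)


class TestRoiAndLbr:
    def _vol(self, data):
        return PETVolume(np.asarray(data, dtype=float), (1.0, 1.0, 1.0))

    def test_constant_disc(self):
        data = np.full((11, 11, 3), 4.2)
        stats = roi_stats(self._vol(data), CircularROI(1, (5, 5), 6.0))
        assert stats.suv_max == 4.2
        assert stats.suv_mean == pytest.approx(4.2)
        assert stats.suv_sd == pytest.approx(0.0, abs=1e-12)

    def test_population_sd_arithmetic(self):
        # a diameter-2mm disc at 1mm pitch covers the 5-voxel plus shape
        data = np.zeros((9, 9, 1))
        data[4, 4, 0] = 2.0
        data[3, 4, 0] = 1.0
        data[5, 4, 0] = 3.0
        data[4, 3, 0] = 2.0
        data[4, 5, 0] = 2.0
        stats = roi_stats(self._vol(data), CircularROI(0, (4, 4), 2.0))
        vals = np.array([2.0, 1.0, 3.0, 2.0, 2.0])
        assert stats.suv_max == 3.0
        assert stats.suv_mean == pytest.approx(vals.mean())
        assert stats.suv_sd == pytest.approx(vals.std())    # population SD

    def test_two_cm_disc_size_at_pet_pitch(self):
        # at 2.34 mm pitch a 20 mm disc has radius ~8.5 voxels
        data = np.zeros((32, 32, 1))
        vol = PETVolume(data, (2.34, 2.34, 2.89))
        roi = CircularROI(0, (15.5, 15.5), 20.0)
        rows, _ = roi.member_indices(data.shape, vol.voxel_size_mm)
        assert 45 <= rows.size <= 60     # ~pi * (10/2.34)^2 = 57 voxels

    def test_roi_transfer_same_member_set(self, rng):
        roi = CircularROI(0, (8, 8), 6.0)
        a = self._vol(rng.random((17, 17, 2)))
        b = self._vol(rng.random((17, 17, 2)))
        np.testing.assert_array_equal(
            np.c_[roi.member_indices(a.data.shape, a.voxel_size_mm)],
            np.c_[roi.member_indices(b.data.shape, b.voxel_size_mm)])

    def test_disc_outside_slice_rejected(self):
        with pytest.raises(ValueError):
            roi_stats(self._vol(np.zeros((8, 8, 1))), CircularROI(0, (1, 1), 8.0))

    def test_lbr(self):
        assert lbr(5.0, 2.0) == pytest.approx(2.5)
        with pytest.raises(ZeroDivisionError):
            lbr(5.0, 0.0)


class TestThresholdAndDelta:
    def test_inclusive_threshold(self):
        vol = np.array([[[4.0, 5.0, 6.0]]])
        np.testing.assert_array_equal(threshold_mask(vol, 5.0),
                                      [[[False, True, True]]])

    def test_delta_zero_for_identical(self, rng):
        x = rng.random((4, 4, 2)) + 5
        mask = threshold_mask(x, 5.0)
        assert np.all(delta_suv(x, x, mask) == 0.0)

    def test_sample_size_equals_mask_cardinality(self, rng):
        a, r = rng.random((6, 6, 3)) * 10, rng.random((6, 6, 3)) * 10
        mask = threshold_mask(r, 5.0)
        assert delta_suv(a, r, mask).size == mask.sum()

    def test_empty_mask_warns_and_returns_empty(self, rng):
        a = rng.random((3, 3, 1))
        with pytest.warns(UserWarning):
            sample = delta_suv(a, a, np.zeros_like(a, dtype=bool))
        assert sample.size == 0


class TestBlandAltman:
    def test_identical_series(self):
        assert bland_altman([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        bias, lo, hi = bland_altman([2, 3, 4], [1, 2, 3])
        assert (bias, lo, hi) == (1.0, 1.0, 1.0)

    def test_matches_hand_summed_oracle(self, rng):
        a, b = rng.random(20), rng.random(20)
        d = a - b
        bias = sum(d) / 20
        sd = math.sqrt(sum((x - bias) ** 2 for x in d) / 19)
        got = bland_altman(a, b)
        assert got[0] == pytest.approx(bias)
        assert got[1] == pytest.approx(bias - 1.96 * sd)
        assert got[2] == pytest.approx(bias + 1.96 * sd)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])
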
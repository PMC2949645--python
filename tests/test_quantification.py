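"""Labeling index arithmetic, cubic calibration, and sample averaging."""

import numpy as np
import pytest

from ihcquant import (
    CalibrationPolynomial,
    aggregate_images,
    apply_calibration,
    fit_calibration,
    labeling_index,
)
from ihcquant.errors import AggregationError, CalibrationError
from ihcquant.quantification import LabelingIndexResult


def mask_of(area_px, shape=(40, 40), offset=0):
    mask = np.zeros(shape, dtype=np.uint8)
    mask.flat[offset : offset + area_px] = 255
    return mask


class TestLabelingIndex:
    def test_pure_h_is_zero_percent(self):
        r = labeling_index(mask_of(0), mask_of(500))
        assert r.raw_index == 0.0

    def test_pure_dab_is_hundred_percent(self):
        r = labeling_index(mask_of(500), mask_of(0))
        assert r.raw_index == 100.0

    def test_disjoint_areas_ratio(self):
        r = labeling_index(mask_of(300), mask_of(700, offset=300))
        assert r.raw_index == pytest.approx(30.0)
        assert r.total_area_px == 1000

    def test_overlap_pixels_count_as_dab_only(self):
        dab = mask_of(400)
        h = mask_of(600)  # first 400 px overlap the DAB mask
        r = labeling_index(dab, h)
        assert r.dab_area_px == 400
        assert r.h_area_px == 200
        assert r.raw_index == pytest.approx(100 * 400 / 600)

    def test_roi_restricts_measurement(self):
        dab = np.zeros((10, 10), dtype=np.uint8)
        h = np.zeros((10, 10), dtype=np.uint8)
        dab[:, :5] = 255
        h[:, 5:] = 255
        roi = np.zeros((10, 10), dtype=np.uint8)
        roi[:, :5] = 255  # only the DAB half
        assert labeling_index(dab, h, roi_mask=roi).raw_index == 100.0

    def test_empty_masks_flagged_not_divided(self):
        r = labeling_index(mask_of(0), mask_of(0))
        assert r.undefined
        assert np.isnan(r.raw_index)
        assert "no nuclear area" in r.warnings

    def test_invariant_under_upscaling(self, rng):
        dab = (rng.random((20, 20)) < 0.3).astype(np.uint8) * 255
        h = (rng.random((20, 20)) < 0.4).astype(np.uint8) * 255
        r1 = labeling_index(dab, h)
        r2 = labeling_index(np.kron(dab, np.ones((2, 2), np.uint8)),
                            np.kron(h, np.ones((2, 2), np.uint8)))
        assert r1.raw_index == pytest.approx(r2.raw_index)


class TestCalibration:
    def test_identity_data_recovers_identity(self):
        x = np.linspace(0, 100, 20)
        poly = fit_calibration(x, x)
        np.testing.assert_allclose(poly.coefficients(), (0, 1, 0, 0), atol=1e-8)
        assert poly.r_squared == pytest.approx(1.0)
        for v in (0.0, 37.5, 100.0):
            assert apply_calibration(v, poly) == pytest.approx(v, abs=1e-6)

    def test_known_cubic_recovered_within_standard_errors(self, rng):
        x = np.linspace(0, 38, 40)
        true = np.array([2.0, 0.8, 0.0, 0.001])
        y = true[0] + true[1] * x + true[3] * x**3 + rng.normal(0, 1, x.size)
        poly = fit_calibration(x, y)
        for c, t, se in zip(poly.coefficients(), true, poly.std_errors):
            assert abs(c - t) <= 3 * se

    def test_underdetermined_and_invalid_inputs(self):
        with pytest.raises(CalibrationError):
            fit_calibration([0, 50, 100], [0, 50, 100])
        with pytest.raises(CalibrationError):
            fit_calibration([0, 1, 2, 150], [0, 1, 2, 3])
        with pytest.raises(CalibrationError):
            fit_calibration([5, 5, 5, 5], [1, 2, 3, 4])  # rank-deficient

    def test_clamping_both_ends(self):
        low = CalibrationPolynomial(-4.0, 0.0, 0.0, 0.0)
        high = CalibrationPolynomial(103.0, 0.0, 0.0, 0.0)
        assert apply_calibration(0.0, low) == 0.0
        assert apply_calibration(100.0, high) == 100.0

    def test_nonmonotone_fit_warns(self):
        x = np.array([0, 10, 20, 30, 40, 50, 60, 100], dtype=float)
        y = np.array([0, 50, 5, 60, 10, 70, 15, 100], dtype=float)
        with pytest.warns(UserWarning, match="not monotone"):
            fit_calibration(x, y)

    def test_coefficient_file_roundtrip(self, tmp_path):
        poly = CalibrationPolynomial(1.5, 0.9, -0.001, 1e-5)
        path = tmp_path / "cal.txt"
        poly.to_file(path)
        again = CalibrationPolynomial.from_file(path)
        assert again.coefficients() == poly.coefficients()


def result(index):
    return LabelingIndexResult(
        dab_area_px=0, h_area_px=0, raw_index=index, corrected_index=index
    )


def undefined_result():
    return LabelingIndexResult(
        dab_area_px=0, h_area_px=0, raw_index=float("nan"),
        corrected_index=float("nan"), undefined=True,
    )


class TestAggregation:
    def test_single_image(self):
        s = aggregate_images([result(42.0)])
        assert s.mean_index == 42.0
        assert s.n_images == 1

    def test_unweighted_mean_and_running_curve(self):
        s = aggregate_images([result(10.0), result(20.0), result(30.0)])
        assert s.mean_index == pytest.approx(20.0)
        assert s.running_mean == pytest.approx((10.0, 15.0, 20.0))

    def test_undefined_results_excluded_with_note(self):
        s = aggregate_images([undefined_result(), result(40.0), result(60.0)])
        assert s.mean_index == pytest.approx(50.0)
        assert s.n_excluded == 1
        assert s.n_images == 2

    def test_all_undefined_is_an_error(self):
        with pytest.raises(AggregationError):
            aggregate_images([undefined_result(), undefined_result()])
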
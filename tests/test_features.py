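import numpy as np
import pytest

from aortafinder.cht import CandidateROI
from aortafinder.core import CircleROI, circle_mask
from aortafinder.features import (
    FEATURE_NAMES,
    histogram_features,
    motion_periodicity_feature,
    motion_periodicity_map,
    mser_features,
    roi_correlation,
    sift_orientation,
    spatial_features,
)
from aortafinder.preprocess import BodyFrame


@pytest.fixture()
def body_setup():
    """Elliptical body mask with its reference frame."""
    rr, cc = np.mgrid[:200, :200]
    mask = ((rr - 100) / 70) ** 2 + ((cc - 100) / 80) ** 2 <= 1
    body = BodyFrame(centroid_rc=(100.0, 100.0), box_side_px=140.0)
    return body, mask


class TestSpatialFeatures:
    def test_roi_at_centroid_projects_to_origin(self, body_setup):
        body, mask = body_setup
        a, b, _ = spatial_features(CircleROI((100.0, 100.0), 10.0), body, mask, (1.0, 1.0))
        assert a == pytest.approx(0.0)
        assert b == pytest.approx(0.0)

    def test_translation_invariance(self, body_setup):
        body, mask = body_setup
        roi = CircleROI((90.0, 120.0), 8.0)
        ref = spatial_features(roi, body, mask, (1.0, 1.0))
        dr, dc = 15, -10
        mask2 = np.roll(mask, (dr, dc), (0, 1))
        body2 = BodyFrame(centroid_rc=(100.0 + dr, 100.0 + dc), box_side_px=140.0)
        roi2 = CircleROI((90.0 + dr, 120.0 + dc), 8.0)
        moved = spatial_features(roi2, body2, mask2, (1.0, 1.0))
        assert moved == pytest.approx(ref, abs=1e-6)

    def test_distance_feature_tracks_depth(self):
        rr, cc = np.mgrid[:200, :200]
        mask = np.hypot(rr - 100, cc - 100) <= 80  # circular body: EDT known
        body = BodyFrame(centroid_rc=(100.0, 100.0), box_side_px=160.0)
        _, _, c_deep = spatial_features(CircleROI((100.0, 100.0), 3.0), body, mask, (1.0, 1.0))
        _, _, c_edge = spatial_features(CircleROI((100.0, 176.0), 3.0), body, mask, (1.0, 1.0))
        assert c_deep > 0.9
        assert c_edge < 0.1

    def test_empty_mask_rejected(self, body_setup):
        body, _ = body_setup
        with pytest.raises(ValueError):
            spatial_features(CircleROI((5.0, 5.0), 2.0), body, np.zeros((10, 10), bool), (1.0, 1.0))


class TestHistogramFeatures:
    def test_constant_input_degenerate_convention(self):
        d, e, f, g, h = histogram_features(np.full(50, 2.5))
        assert (d, e, f, g, h) == (2.5, 0.0, 0.0, 0.0, 0.0)

    def test_uniform_histogram_has_eight_bits(self):
        # one sample per bin: -sum (1/256) log2(1/256) = 8
        values = np.arange(256, dtype=float)
        *_, h = histogram_features(values, hist_range=(-0.5, 255.5))
        assert h == pytest.approx(8.0)

    def test_symmetric_two_point_moments(self):
        values = np.array([0.0, 1.0] * 32)
        d, e, f, g, _ = histogram_features(values)
        assert d == pytest.approx(0.5)
        assert e == pytest.approx(0.25)
        assert f == pytest.approx(0.0)
        assert g == pytest.approx(1.0)

    def test_shift_invariance_of_central_moments(self):
        rng = np.random.default_rng(0)
        v = rng.random(200)
        d1, e1, f1, g1, _ = histogram_features(v)
        d2, e2, f2, g2, _ = histogram_features(v + 10.0)
        assert d2 == pytest.approx(d1 + 10.0)
        assert (e2, f2, g2) == pytest.approx((e1, f1, g1))

    def test_entropy_invariant_to_bin_permutation(self):
        # entropy depends only on the histogram counts, not bin identity
        v = np.repeat([0.1, 0.4, 0.9], [10, 30, 60]).astype(float)
        *_, h1 = histogram_features(v, hist_range=(0, 1))
        v_permuted = np.repeat([0.9, 0.1, 0.4], [10, 30, 60]).astype(float)
        *_, h2 = histogram_features(v_permuted, hist_range=(0, 1))
        assert h1 == pytest.approx(h2)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.array([1.0]))


class TestRoiCorrelation:
    def test_patch_equal_to_mask_scores_one(self):
        roi = CircleROI((32.0, 32.0), 10.0)
        frame = circle_mask(roi, 64, 64, 1.0).astype(float)
        assert roi_correlation(frame, roi, (1.0, 1.0)) == pytest.approx(1.0)

    def test_inverted_patch_scores_minus_one(self):
        roi = CircleROI((32.0, 32.0), 10.0)
        frame = 1.0 - circle_mask(roi, 64, 64, 1.0).astype(float)
        assert roi_correlation(frame, roi, (1.0, 1.0)) == pytest.approx(-1.0)

    def test_flat_patch_flagged_zero(self):
        roi = CircleROI((32.0, 32.0), 5.0)
        assert roi_correlation(np.ones((64, 64)), roi, (1.0, 1.0)) == 0.0


class TestSiftOrientation:
    def test_ramp_along_columns_has_zero_orientation(self):
        frame = np.tile(np.arange(64, dtype=float), (64, 1))
        j = sift_orientation(frame, (32.0, 32.0), scale_px=6.0)
        bin_width = 2 * np.pi / 36
        assert j < bin_width or j > 2 * np.pi - bin_width

    def test_rotation_shifts_orientation_by_quarter_turn(self):
        rng = np.random.default_rng(2)
        frame = np.cumsum(rng.random((64, 64)), axis=1)
        j1 = sift_orientation(frame, (32.0, 32.0), scale_px=6.0)
        j2 = sift_orientation(np.rot90(frame, k=-1), (32.0, 32.0), scale_px=6.0)
        bin_width = 2 * np.pi / 36
        shift = np.mod(j2 - j1, 2 * np.pi)
        assert min(abs(shift - np.pi / 2), abs(shift - np.pi / 2 - 2 * np.pi)) <= bin_width + 1e-9

    def test_flat_window_flagged_zero(self):
        assert sift_orientation(np.ones((32, 32)), (16.0, 16.0), 4.0) == 0.0

    def test_result_in_circle_range(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            j = sift_orientation(rng.random((48, 48)), (24.0, 24.0), 5.0)
            assert 0.0 <= j < 2 * np.pi


class TestMotionPeriodicity:
    def _pulsing_stack(self, pulse=True, n=32):
        rr, cc = np.mgrid[:64, :64].astype(float)
        stack = np.empty((64, 64, n))
        for k in range(n):
            r = 10.0 * (1 + (0.1 if pulse else 0.0) * np.sin(2 * np.pi * k / n))
            stack[:, :, k] = 0.1 + 0.9 * (np.hypot(rr - 32, cc - 32) <= r)
        return stack

    def test_static_series_scores_zero(self):
        stack = np.ones((32, 32, 16)) * np.random.default_rng(0).random((32, 32))[..., None]
        roi = CircleROI((16.0, 16.0), 5.0)
        assert motion_periodicity_feature(stack, roi, (1.0, 1.0)) == 0.0

    def test_pulsing_vessel_scores_high_on_true_circle(self):
        stack = self._pulsing_stack()
        k = motion_periodicity_feature(stack, CircleROI((32.0, 32.0), 10.0), (1.0, 1.0))
        assert k >= 0.5

    def test_candidate_far_from_pulsation_scores_low(self):
        stack = self._pulsing_stack()
        k = motion_periodicity_feature(stack, CircleROI((8.0, 55.0), 5.0), (1.0, 1.0))
        assert k <= 0.1

    def test_map_marks_only_rim(self):
        stack = self._pulsing_stack()
        mp = motion_periodicity_map(stack)
        er, ec = np.nonzero(mp)
        assert mp.any()
        assert np.all(np.abs(np.hypot(er - 32, ec - 32) - 10.0) <= 3.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            motion_periodicity_map(np.zeros((8, 8, 4)))


class TestMserFeatures:
    def test_disc_matching_roi(self):
        # r >= 15 px keeps hull-rasterization solidity loss under 5%
        roi = CircleROI((60.0, 60.0), 15.0)
        frame = 0.1 + 0.8 * circle_mask(roi, 120, 120, 1.0).astype(float)
        frame += np.random.default_rng(0).normal(0, 0.005, frame.shape)
        n, o, p, q, r = mser_features(frame, roi, (1.0, 1.0))
        assert n >= 1
        assert o >= 0.95
        assert p <= 0.05
        assert q >= 0.95
        assert r <= 0.3

    def test_elongated_bar_is_eccentric(self):
        frame = np.full((80, 80), 0.1)
        frame[38:42, 10:70] = 1.0  # 4 x 60 bar
        frame += np.random.default_rng(1).normal(0, 0.005, frame.shape)
        roi = CircleROI((40.0, 40.0), 8.0)
        n, o, p, q, r = mser_features(frame, roi, (1.0, 1.0))
        assert n >= 1
        assert r >= 0.9

    def test_uniform_window_degenerate_defaults(self):
        roi = CircleROI((40.0, 40.0), 8.0)
        n, o, p, q, r = mser_features(np.ones((80, 80)), roi, (1.0, 1.0))
        assert (n, o, p, q, r) == (0.0, 0.0, 0.0, 1.0, 0.0)


class TestFeatureVectorOnPhantom:
    def test_canonical_order_and_length(self):
        assert len(FEATURE_NAMES) == 18
        assert FEATURE_NAMES[0] == "diagBodyRFcentreX"
        assert FEATURE_NAMES[-1] == "MSEReccentricity"

    def test_bounds_hold_for_all_phantom_candidates(self, processed):
        X = processed.X
        assert X.shape[1] == 18
        idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
        assert np.all((X[:, idx["normDistMask"]] >= 0) & (X[:, idx["normDistMask"]] <= 1))
        assert np.all((X[:, idx["MPmaskDSC"]] >= 0) & (X[:, idx["MPmaskDSC"]] <= 1))
        assert np.all((X[:, idx["CHTmetric"]] > 0) & (X[:, idx["CHTmetric"]] <= 1))
        assert np.all((X[:, idx["MSERmaskDSC"]] >= 0) & (X[:, idx["MSERmaskDSC"]] <= 1))
        assert np.all((X[:, idx["roiCorrelation"]] >= -1) & (X[:, idx["roiCorrelation"]] <= 1))
        assert np.all((X[:, idx["SIFTorientation"]] >= 0) & (X[:, idx["SIFTorientation"]] < 2 * np.pi))
        assert np.all((X[:, idx["CHTradius"]] >= 6) & (X[:, idx["CHTradius"]] <= 36))
        assert np.all(X[:, idx["MSERregions"]] >= 0)
        assert np.all(X[:, idx["MSERregions"]] == np.round(X[:, idx["MSERregions"]]))
        assert np.all(X[:, idx["MSERnotOverlap"]] >= 0)
        assert np.all((X[:, idx["MSERsolidity"]] > 0) & (X[:, idx["MSERsolidity"]] <= 1))
        assert np.all((X[:, idx["MSEReccentricity"]] >= 0) & (X[:, idx["MSEReccentricity"]] < 1))
        assert np.all(X[:, idx["intensityVar"]] >= 0)
        assert np.all(X[:, idx["intensityKurtosis"]] >= 0)
        assert np.all(X[:, idx["imageEntropy"]] >= 0)
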
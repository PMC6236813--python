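"""Otsu thresholding, component labelling/filtering, and marker detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fidqa import detection, phantom, scaling
from fidqa.detection import MarkerBlob, RoiMask
from fidqa.errors import (
    DegenerateHistogramError,
    DetectionCountError,
    InvalidParameterError,
)
from fidqa.phantom import _disc_coverage  # rendering primitive reused for the property test

from conftest import default_roi, make_config, matched_error_px


def brute_force_otsu(values: np.ndarray) -> float:
    """Independent oracle: exhaustive search over all 8-bit cut points."""
    best_sigma, best_t = -1.0, None
    v = np.asarray(values, dtype=float)
    for t in range(256):
        fg = v > t
        if fg.all() or (~fg).all():
            continue
        w0, w1 = (~fg).mean(), fg.mean()
        sigma_b = w0 * w1 * (v[~fg].mean() - v[fg].mean()) ** 2
        if sigma_b > best_sigma:  # strict: first maximum = lowest threshold
            best_sigma, best_t = sigma_b, t
    return float(best_t)


class TestOtsu:
    def test_bimodal_sample_separated_exactly(self):
        sample = np.concatenate([np.zeros(100), np.full(20, 200.0)])
        thr = detection.otsu_threshold(sample)
        assert 0 <= thr < 200
        assert np.array_equal(sample > thr, sample == 200.0)

    def test_matches_exhaustive_search_on_random_8bit(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            v = rng.integers(0, 256, size=int(rng.integers(20, 400))).astype(float)
            if np.unique(v).size < 2:
                continue
            assert detection.otsu_threshold(v) == brute_force_otsu(v)

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            detection.otsu_threshold(np.full(50, 7.0))


class TestComponents:
    def test_diagonal_pixels_are_one_component(self):
        binary = np.zeros((5, 5), bool)
        binary[1, 1] = binary[2, 2] = True
        blobs = detection.label_and_filter_components(binary, 1, 10)
        assert len(blobs) == 1 and blobs[0].area == 2

    def test_area_bounds_discard_distractor_and_specks(self):
        binary = np.zeros((60, 120), bool)
        binary[5:9, 5:10] = True  # 20 px marker-like
        binary[20:24, 20:25] = True
        binary[40:44, 40:45] = True
        binary[10:30, 60:80] = True  # 400 px distractor
        binary[50, 100] = True  # isolated speck
        blobs = detection.label_and_filter_components(binary, 2, 100)
        assert len(blobs) == 3
        assert all(b.area == 20 for b in blobs)

    def test_blobs_sorted_by_row_then_col(self):
        binary = np.zeros((30, 30), bool)
        binary[20:22, 2:4] = True
        binary[2:4, 20:22] = True
        binary[2:4, 2:4] = True
        blobs = detection.label_and_filter_components(binary, 1, 10)
        coms = [b.com_px for b in blobs]
        assert coms == sorted(coms, key=lambda c: (c[1], c[0]))


class TestComponentCom:
    @pytest.mark.parametrize(
        "rows, cols, expected",
        [
            ([10], [20], (20.0, 10.0)),
            ([10, 10, 11, 11], [20, 21, 20, 21], (20.5, 10.5)),
            ([0, 0, 1], [0, 1, 0], (1.0 / 3.0, 1.0 / 3.0)),
        ],
    )
    def test_unweighted_centroid(self, rows, cols, expected):
        blob = MarkerBlob(
            rows=np.array(rows), cols=np.array(cols), area=len(rows),
            bounding_box=(0, 0, 2, 2), com_px=(0.0, 0.0),
        )
        assert detection.component_com(blob, spacing=1.0) == pytest.approx(expected)

    def test_spacing_converts_to_mm(self):
        blob = MarkerBlob(
            rows=np.array([4]), cols=np.array([8]), area=1,
            bounding_box=(8, 4, 1, 1), com_px=(8.0, 4.0),
        )
        assert detection.component_com(blob, spacing=0.5) == pytest.approx((4.0, 2.0))

    def test_empty_blob_rejected(self):
        blob = MarkerBlob(np.array([]), np.array([]), 0, (0, 0, 0, 0), (0.0, 0.0))
        with pytest.raises(InvalidParameterError):
            detection.component_com(blob, 1.0)


class TestDetectMarkers:
    def _rescaled(self, ckv, truth):
        est = scaling.compute_scale_factor(truth.scale_factor, 1.0)
        return scaling.rescale_to_reference(
            ckv.presented_ap(), est, truth.pixel_spacing_drr
        )

    def test_drr_markers_within_half_pixel(self, clean_pair):
        drr, _, truth = clean_pair
        cloud = detection.detect_markers_drr(drr, default_roi(truth, drr.shape))
        assert len(cloud) == 3
        assert matched_error_px(cloud.points, truth.drr_marker_com,
                                truth.pixel_spacing_drr) < 0.5

    def test_wrong_marker_count_reports_found(self):
        cfg = make_config(n_markers=2, marker_positions_mm=np.array(
            [[92.0, 102.0], [114.0, 102.0]]))
        drr, _, truth = phantom.generate_phantom_pair(cfg)
        with pytest.raises(DetectionCountError, match="found 2"):
            detection.detect_markers_drr(drr, default_roi(truth, drr.shape), expected_n=3)

    def test_oversized_distractor_is_ignored(self):
        drr, _, truth = phantom.generate_phantom_pair(make_config(distractors=1))
        cloud = detection.detect_markers_drr(drr, default_roi(truth, drr.shape, 20.0))
        assert len(cloud) == 3
        assert matched_error_px(cloud.points, truth.drr_marker_com,
                                truth.pixel_spacing_drr) < 0.5

    def _ckv_roi(self, truth, rescaled):
        from fidqa.pipeline import roi_around_markers

        return roi_around_markers(
            truth.ckv_marker_com, truth.pixel_spacing_drr, rescaled.shape
        )

    def test_ckv_markers_within_half_pixel_noise_free(self, clean_pair):
        _, ckv, truth = clean_pair
        rescaled = self._rescaled(ckv, truth)
        cloud = detection.detect_markers_ckv(rescaled, self._ckv_roi(truth, rescaled))
        assert matched_error_px(cloud.points, truth.ckv_marker_com,
                                truth.pixel_spacing_drr) < 0.5

    def test_ckv_with_five_percent_noise_within_one_pixel(self):
        _, ckv, truth = phantom.generate_phantom_pair(make_config(noise_sd=0.05, seed=21))
        rescaled = self._rescaled(ckv, truth)
        cloud = detection.detect_markers_ckv(rescaled, self._ckv_roi(truth, rescaled))
        assert matched_error_px(cloud.points, truth.ckv_marker_com,
                                truth.pixel_spacing_drr) < 1.0

    def test_inverted_polarity_suppresses_markers(self, clean_pair):
        # feeding the bright-marker DRR through the dark-marker path must not
        # yield the expected count: the markers end up in the dark class
        drr, _, truth = clean_pair
        with pytest.raises((DetectionCountError, DegenerateHistogramError)):
            detection.detect_markers_ckv(drr, default_roi(truth, drr.shape))

    @pytest.mark.parametrize("shift_px", [(7, -5), (-12, 9)])
    def test_detection_is_translation_equivariant(self, shift_px):
        base_cfg = make_config()
        s = base_cfg.pixel_spacing_drr
        shift_mm = np.array(shift_px) * s
        center = np.array([base_cfg.image_shape_drr[1], base_cfg.image_shape_drr[0]]) / 2 * s
        moved_pos = phantom._default_positions(3, center, base_cfg.marker_spacing) + shift_mm
        drr0, _, t0 = phantom.generate_phantom_pair(base_cfg)
        drr1, _, t1 = phantom.generate_phantom_pair(
            make_config(marker_positions_mm=moved_pos)
        )
        c0 = detection.detect_markers_drr(drr0, default_roi(t0, drr0.shape), threshold=0.8)
        c1 = detection.detect_markers_drr(drr1, default_roi(t1, drr1.shape), threshold=0.8)
        np.testing.assert_allclose(c1.points - c0.points,
                                   np.tile(shift_mm, (3, 1)), atol=1e-9)


class TestSubPixelCom:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cx=st.floats(20.0, 28.0),
        cy=st.floats(20.0, 28.0),
        radius=st.floats(3.0, 6.0),
    )
    def test_binarized_disc_centroid_within_half_pixel(self, cx, cy, radius):
        # a rendered disc, binarized at mid-level, must have its binary
        # centroid within 0.5 px of the geometric centre at any sub-pixel
        # placement
        raster = np.full((48, 48), 0.5)
        sl_r, sl_c, cov = _disc_coverage(raster.shape, (cx, cy), radius)
        raster[sl_r, sl_c] = raster[sl_r, sl_c] * (1 - cov) + 1.0 * cov
        blobs = detection.label_and_filter_components(raster > 0.75, 1, 2000)
        assert len(blobs) == 1
        com = blobs[0].com_px
        assert abs(com[0] - cx) < 0.5 and abs(com[1] - cy) < 0.5
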
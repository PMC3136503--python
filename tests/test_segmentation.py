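import numpy as np
import pytest
from scipy import ndimage

from fatrack import FrameImage, high_pass_filter, measure_blobs, threshold_mask, water_segment
from fatrack.segmentation import disk_kernel, segment_frame
from fatrack import AnalysisConfig


class TestHighPassFilter:
    def test_constant_image_maps_to_zero(self):
        out = high_pass_filter(FrameImage(np.full((40, 40), 0.7)), 11)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_round_kernel_pixel_count_at_default_radius(self):
        # radius 11 px: the round kernel covers 377 pixels (diameter 4.95 µm
        # at 0.225 µm/px)
        k = disk_kernel(11)
        assert int(round(1 / k.max())) == 377
        assert k.shape == (23, 23)

    def test_single_bright_pixel_center_response(self):
        # center value v(1 - 1/K) against a direct convolution oracle
        img = np.zeros((41, 41))
        img[20, 20] = 0.8
        out = high_pass_filter(FrameImage(img), 5)
        K = (disk_kernel(5) > 0).sum()
        assert out[20, 20] == pytest.approx(0.8 * (1 - 1 / K), rel=1e-9)
        # oracle: full convolution with edge padding
        kernel = disk_kernel(5)
        padded = np.pad(img, 5, mode="edge")
        oracle = img - ndimage.convolve(img, kernel, mode="nearest")
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_radius_too_large_raises(self):
        with pytest.raises(ValueError):
            high_pass_filter(FrameImage(np.zeros((10, 10))), 11)


class TestThresholdMask:
    def test_zero_image_empty_mask(self):
        assert threshold_mask(np.zeros((5, 5)), 0.1).sum() == 0

    def test_counts_pixels_at_or_above_threshold(self):
        img = np.zeros((5, 5))
        img[0, 0] = img[1, 1] = img[2, 2] = 0.5
        assert threshold_mask(img, 0.1).sum() == 3

    def test_mask_shrinks_monotonically_in_threshold(self, rng):
        img = rng.uniform(0, 0.2, (50, 50))
        sizes = [threshold_mask(img, t).sum() for t in (0.05, 0.075, 0.10)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((5, 5)), 0.0)


def _steepest_ascent_labels(smoothed, mask, labels):
    """Oracle: climb each mask pixel to its attracting maximum and check
    that all pixels draining to one peak share one label."""
    h, w = smoothed.shape
    peak_to_labels = {}
    for r, c in zip(*np.nonzero(mask)):
        rr, cc = r, c
        while True:
            best = (smoothed[rr, cc], rr, cc)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and smoothed[nr, nc] > best[0]:
                        best = (smoothed[nr, nc], nr, nc)
            if (best[1], best[2]) == (rr, cc):
                break
            rr, cc = best[1], best[2]
        peak_to_labels.setdefault((rr, cc), set()).add(labels[r, c])
    return peak_to_labels


class TestWaterSegment:
    def test_single_disc_single_label_no_hole(self):
        yy, xx = np.mgrid[0:30, 0:30]
        img = 0.4 * np.exp(-((yy - 15) ** 2 + (xx - 15) ** 2) / 18.0)
        mask = img > 0.1
        labels = water_segment(mask, FrameImage(img))
        assert labels.max() == 1
        filled = ndimage.binary_fill_holes(labels == 1)
        assert np.array_equal(filled, labels == 1)

    def test_dumbbell_partition_matches_steepest_ascent_oracle(self):
        yy, xx = np.mgrid[0:40, 0:40]
        img = (0.5 * np.exp(-((yy - 20) ** 2 + (xx - 12) ** 2) / 18.0)
               + 0.5 * np.exp(-((yy - 20) ** 2 + (xx - 27) ** 2) / 18.0))
        mask = img > 0.05
        labels = water_segment(mask, FrameImage(img))
        assert labels.max() == 2
        smoothed = ndimage.gaussian_filter(img, 1.0)
        basins = _steepest_ascent_labels(smoothed, mask, labels)
        assert len(basins) == 2
        # each attraction basin maps onto exactly one watershed label
        assert all(len(v) == 1 for v in basins.values())
        assert set.union(*basins.values()) == {1, 2}

    def test_bridge_pixel_assigned_to_closer_centroid(self):
        img = np.zeros((20, 32))
        img[5:12, 2:9] = 0.4       # 49 px, centroid col 5
        img[5:12, 11:18] = 0.4     # 49 px, centroid col 14
        img[8, 9] = 0.3            # single bridge pixel: 4 px from A, 5 from B
        img[8, 10] = 0.0
        # connect bridge to B as well
        img[8, 10] = 0.3
        mask = img > 0.05
        labels = water_segment(mask, FrameImage(img), large_adhesion_px=40)
        a, b = labels[8, 5], labels[8, 14]
        assert a != b
        assert labels[8, 9] == a      # closer to A's centroid
        assert labels[8, 10] == b     # closer to B's centroid

    def test_hole_filled_with_owner_label(self):
        yy, xx = np.mgrid[0:30, 0:30]
        img = 0.4 * np.exp(-((yy - 15) ** 2 + (xx - 15) ** 2) / 50.0)
        img[18, 15] = 0.0         # off-peak interior hole, below threshold
        mask = img > 0.1
        assert not mask[18, 15]
        labels = water_segment(mask, FrameImage(img))
        assert labels.max() == 1
        assert labels[18, 15] == 1

    def test_every_mask_pixel_labeled_exactly_once(self, rng):
        img = np.clip(rng.normal(0.1, 0.08, (60, 60)), 0, 1)
        mask = img > 0.2
        labels = water_segment(mask, FrameImage(img))
        # every mask pixel carries a label; extra labeled pixels can only
        # be filled interior holes
        assert (labels[mask] > 0).all()
        extra = (labels > 0) & ~mask
        assert (extra <= (ndimage.binary_fill_holes(mask) & ~mask)).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            water_segment(np.zeros((5, 5), bool), FrameImage(np.zeros((6, 6))))


class TestMeasureBlobs:
    def _label_single(self, rows, cols, shape=(40, 40), value=0.5):
        img = np.zeros(shape)
        labels = np.zeros(shape, dtype=np.int32)
        img[rows, cols] = value
        labels[rows, cols] = 1
        return labels, FrameImage(img)

    def test_disc_axial_ratio_near_one(self):
        yy, xx = np.mgrid[0:31, 0:31]
        disc = (yy - 15) ** 2 + (xx - 15) ** 2 <= 64
        rr, cc = np.nonzero(disc)
        labels, frame = self._label_single(rr, cc)
        blob = measure_blobs(labels, frame)[0]
        assert blob.axial_ratio == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("n", [3, 5, 9, 15])
    def test_line_axial_ratio_grows_with_length(self, n):
        # moments oracle: a 1xn line with unit-square pixel correction has
        # axial ratio exactly n
        rows = np.full(n, 10)
        cols = np.arange(5, 5 + n)
        labels, frame = self._label_single(rows, cols)
        blob = measure_blobs(labels, frame)[0]
        assert blob.axial_ratio == pytest.approx(n, rel=1e-6)

    def test_area_calibration_40px_is_1_85_um2(self):
        rows, cols = np.divmod(np.arange(40), 8)
        labels, frame = self._label_single(rows + 5, cols + 5)
        frame.pixel_size_um = 0.215
        blob = measure_blobs(labels, frame)[0]
        assert blob.area_px == 40
        assert blob.area_um2 == pytest.approx(1.85, abs=0.01)

    def test_mean_intensity_on_raw_frame(self):
        labels, frame = self._label_single(np.array([5, 5]), np.array([5, 6]), value=0.3)
        blob = measure_blobs(labels, frame)[0]
        assert blob.mean_intensity == pytest.approx(0.3)

    def test_empty_labels_empty_list(self):
        assert measure_blobs(np.zeros((5, 5), dtype=np.int32), FrameImage(np.zeros((5, 5)))) == []


class TestSegmentFrame:
    def test_count_non_increasing_in_threshold(self, rng):
        img = np.clip(rng.normal(0.05, 0.05, (80, 80)), 0, 1)
        yy, xx = np.mgrid[0:80, 0:80]
        for cy in (20, 40, 60):
            img[(yy - cy) ** 2 + (xx - 40) ** 2 <= 9] += 0.3
        img = np.clip(img, 0, 1)
        frame = FrameImage(img)
        counts = [
            len(segment_frame(frame, AnalysisConfig(detection_threshold=t)))
            for t in (0.05, 0.075, 0.10)
        ]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[-1] >= 3

    def test_detects_planted_count_for_bright_adhesions(self, small_stationary):
        # every planted adhesion with intensity >= 0.21 and radius >= 1.5 px
        # yields a blob at its center in every live frame
        movie, result, _ = small_stationary
        for truth in movie.truth:
            for idx, t in enumerate(truth.life_frames):
                r, c = (int(round(v)) for v in truth.centers[idx])
                hit = any(
                    ((b.rows == r) & (b.cols == c)).any()
                    for b in result.frame_blobs[t]
                )
                assert hit, f"adhesion {truth.adhesion_id} missing in frame {t}"
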
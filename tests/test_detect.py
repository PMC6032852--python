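"""LoG feature, marker extraction, watershed segmentation and box postprocessing."""

import numpy as np
import pytest

from irf_cellfinder.core_io import BBox, DetectionSet, Image2D
from irf_cellfinder.detect import (
    DetectConfig,
    LabelMap,
    background_markers,
    cell_markers,
    detect_cells,
    gradient_magnitude,
    labels_to_boxes,
    log_feature,
    postprocess_boxes,
    segment,
)
from irf_cellfinder.preprocess import PreprocessConfig


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    r = np.arange(shape[0])[:, None] - center[0]
    c = np.arange(shape[1])[None, :] - center[1]
    return amplitude * np.exp(-(r**2 + c**2) / (2.0 * sigma**2))


class TestLogFeature:
    def test_constant_image_gives_zero_response(self):
        out = log_feature(Image2D(np.full((32, 32), 0.7)), sigma=7.0)
        # zero up to the Gaussian-kernel truncation error of the filter
        np.testing.assert_allclose(out.pixels, 0.0, atol=5e-3)

    def test_scale_selection_peaks_at_matching_sigma(self):
        """Scale-normalized response of a sigma=7 blob is maximal at
        filter scale 7 among {3, 7, 14}."""
        img = Image2D(gaussian_blob((128, 128), (64, 64), sigma=7.0))
        responses = {s: log_feature(img, sigma=s).pixels[64, 64] for s in (3.0, 7.0, 14.0)}
        assert max(responses, key=responses.get) == 7.0

    def test_bright_blob_center_response_positive_and_above_border(self):
        img = Image2D(gaussian_blob((64, 64), (32, 32), sigma=5.0))
        feat = log_feature(img, sigma=5.0).pixels
        assert feat[32, 32] > 0
        assert feat[32, 32] > feat[1, 1]


class TestCellMarkers:
    def test_grid_of_distinct_values_sort_oracle(self):
        feature = Image2D(np.arange(1.0, 101.0).reshape(10, 10))
        mask = cell_markers(feature, quantile=0.92)
        assert mask.sum() == 8
        assert set(feature.pixels[mask]) == set(range(93, 101))

    @pytest.mark.parametrize("q", [0.5, 0.92, 0.99])
    def test_true_fraction_tracks_quantile(self, q, rng):
        feature = Image2D(rng.normal(size=(1000, 1000)))
        frac = cell_markers(feature, quantile=q).mean()
        assert abs(frac - (1 - q)) < 1e-3

    def test_ties_at_threshold_are_included(self):
        px = np.zeros((10, 10))
        px[:2] = 5.0  # 20 tied pixels at the top
        mask = cell_markers(Image2D(px), quantile=0.92)
        assert mask.sum() == 20

    def test_quantile_near_zero_selects_everything(self, rng):
        feature = Image2D(rng.permutation(100.0 * np.arange(1, 65)).reshape(8, 8))
        assert cell_markers(feature, quantile=1e-300).all()

    def test_monotone_in_quantile(self, rng):
        feature = Image2D(rng.normal(size=(64, 64)))
        counts = [cell_markers(feature, q).sum() for q in (0.5, 0.7, 0.9, 0.97)]
        assert counts == sorted(counts, reverse=True)

    def test_constant_feature_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            cell_markers(Image2D(np.ones((8, 8))), quantile=0.92)


class TestGradientMagnitude:
    def test_constant_gives_zero(self):
        out = gradient_magnitude(Image2D(np.full((16, 16), 3.0)))
        np.testing.assert_allclose(out.pixels, 0.0)

    def test_unit_ramp_calibration(self):
        ramp = Image2D(np.tile(np.arange(32.0), (32, 1)))
        g = gradient_magnitude(ramp).pixels
        np.testing.assert_allclose(g[2:-2, 2:-2], 1.0, atol=1e-12)

    def test_isotropy_under_rotation(self, rng):
        px = rng.uniform(size=(48, 48))
        g = gradient_magnitude(Image2D(px)).pixels
        g_rot = gradient_magnitude(Image2D(np.rot90(px))).pixels
        np.testing.assert_allclose(np.rot90(g), g_rot, atol=1e-12)

    def test_nonnegative(self, rng):
        assert gradient_magnitude(Image2D(rng.normal(size=(32, 32)))).pixels.min() >= 0


class TestBackgroundMarkers:
    def test_two_blobs_midline(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[28:36, 8:16] = True
        mask[28:36, 48:56] = True
        bg = background_markers(mask)
        # ridge of the distance transform passes between the blobs
        assert bg[28:36, 30:34].any()
        assert not (bg & mask).any()

    def test_disjoint_from_cell_markers_random(self, rng):
        for _ in range(5):
            mask = rng.random((48, 48)) > 0.85
            if not mask.any() or mask.all():
                continue
            assert not (background_markers(mask) & mask).any()

    def test_single_blob_gives_connected_border_touching_set(self):
        import scipy.ndimage as ndi

        mask = np.zeros((64, 64), dtype=bool)
        mask[28:36, 28:36] = True
        bg = background_markers(mask)
        _, n = ndi.label(bg, structure=np.ones((3, 3)))
        assert n == 1
        border_band = np.zeros_like(bg)
        border_band[:4] = border_band[-4:] = True
        border_band[:, :4] = border_band[:, -4:] = True
        assert (bg & border_band).any()

    def test_degenerate_masks_error(self):
        with pytest.raises(ValueError):
            background_markers(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            background_markers(np.ones((8, 8), dtype=bool))


class TestSegment:
    @staticmethod
    def two_disk_scene():
        img = np.zeros((96, 96))
        yy, xx = np.mgrid[:96, :96]
        img += ((yy - 30) ** 2 + (xx - 25) ** 2 < 144) * 1.0
        img += ((yy - 65) ** 2 + (xx - 70) ** 2 < 144) * 1.0
        feat = log_feature(Image2D(img), sigma=6.0)
        cells = cell_markers(feat, quantile=0.95)
        bg = background_markers(cells)
        grad = gradient_magnitude(feat)
        return grad, cells, bg

    def test_two_separated_disks_give_two_labels(self):
        grad, cells, bg = self.two_disk_scene()
        lm = segment(grad, cells, bg)
        assert lm.n_labels == np.max(lm.labels)
        import scipy.ndimage as ndi

        # exactly one watershed region per disk
        n_marker_components = ndi.label(cells)[1]
        assert lm.n_labels == n_marker_components == 2

    def test_every_label_contains_a_cell_marker(self):
        grad, cells, bg = self.two_disk_scene()
        lm = segment(grad, cells, bg)
        for lab in range(1, lm.n_labels + 1):
            assert cells[lm.labels == lab].any()

    def test_no_cell_markers_gives_empty_map(self):
        grad, cells, bg = self.two_disk_scene()
        lm = segment(grad, np.zeros_like(cells), bg)
        assert lm.n_labels == 0

    def test_overlapping_markers_rejected(self):
        grad, cells, bg = self.two_disk_scene()
        with pytest.raises(ValueError):
            segment(grad, cells, cells)


class TestBoxes:
    def test_tight_box_per_label(self):
        labels = np.zeros((8, 12), dtype=np.int32)
        labels[2:5, 3:10] = 1
        dets = labels_to_boxes(LabelMap(labels))
        assert dets.boxes == (BBox(2, 3, 5, 10, label=1),)

    def test_empty_label_map(self):
        assert len(labels_to_boxes(LabelMap(np.zeros((4, 4), dtype=np.int32)))) == 0

    def test_one_box_per_distinct_label(self, rng):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:6, 2:6] = 1
        labels[10:14, 10:20] = 2
        labels[20:30, 5:9] = 5
        dets = labels_to_boxes(LabelMap(labels))
        assert len(dets) == 3
        assert sorted(b.label for b in dets.boxes) == [1, 2, 5]


class TestPostprocess:
    CFG = DetectConfig(min_area_px=100, max_area_px=20000, merge_overlap=0.5)

    @staticmethod
    def brute_force_merge(boxes, threshold):
        """Reference pairwise merger: repeat until no pair overlaps enough."""
        boxes = list(boxes)
        while True:
            for i in range(len(boxes)):
                for j in range(i + 1, len(boxes)):
                    inter = boxes[i].intersection_area(boxes[j])
                    if inter / min(boxes[i].area, boxes[j].area) >= threshold:
                        merged = boxes[i].union_box(boxes[j])
                        boxes = [b for k, b in enumerate(boxes) if k not in (i, j)] + [merged]
                        break
                else:
                    continue
                break
            else:
                return boxes

    def test_majority_overlap_merges_to_union(self):
        # second box shares 60% of its own area with the first
        a, b = BBox(0, 0, 20, 20), BBox(10, 8, 20, 28)
        assert a.intersection_area(b) / min(a.area, b.area) == pytest.approx(0.6)
        out = postprocess_boxes(DetectionSet(boxes=(a, b)), self.CFG)
        assert out.boxes == (BBox(0, 0, 20, 28),)

    def test_merge_agrees_with_brute_force_on_random_sets(self, rng):
        from conftest import random_boxes

        for _ in range(30):
            boxes = random_boxes(rng, int(rng.integers(2, 8)), shape=(40, 40))
            cfg = DetectConfig(min_area_px=1, max_area_px=10**6, merge_overlap=0.5)
            ours = set(postprocess_boxes(DetectionSet(boxes=tuple(boxes)), cfg).boxes)
            ref = {BBox(b.row0, b.col0, b.row1, b.col1) for b in self.brute_force_merge(boxes, 0.5)}
            assert {(b.row0, b.col0, b.row1, b.col1) for b in ours} == {
                (b.row0, b.col0, b.row1, b.col1) for b in ref
            }

    def test_small_boxes_dropped(self):
        out = postprocess_boxes(DetectionSet(boxes=(BBox(0, 0, 2, 2),)), self.CFG)
        assert len(out) == 0

    def test_disjoint_boxes_untouched(self):
        boxes = (BBox(0, 0, 15, 15), BBox(20, 20, 40, 40))
        out = postprocess_boxes(DetectionSet(boxes=boxes), self.CFG)
        assert set(out.boxes) == set(boxes)

    def test_result_sorted_by_descending_area(self):
        boxes = (BBox(0, 0, 11, 11), BBox(20, 20, 40, 40), BBox(50, 50, 62, 62))
        out = postprocess_boxes(DetectionSet(boxes=boxes), self.CFG)
        areas = [b.area for b in out.boxes]
        assert areas == sorted(areas, reverse=True)

    def test_oversized_background_basin_cannot_absorb_cells(self):
        """A near-image-sized background basin is discarded before merging,
        so it does not swallow the cell boxes it encloses."""
        giant = BBox(0, 0, 500, 500, label=1)  # area >> max_area_px
        cell_a = BBox(40, 40, 100, 100, label=2)
        cell_b = BBox(300, 300, 360, 370, label=3)
        out = postprocess_boxes(DetectionSet(boxes=(giant, cell_a, cell_b)), self.CFG)
        assert {(b.row0, b.col0, b.row1, b.col1) for b in out.boxes} == {
            (40, 40, 100, 100), (300, 300, 360, 370)
        }

    def test_oversegmentation_repair(self):
        """Two watershed fragments of one cell (heavily overlapping boxes)
        come out as a single covering box."""
        top = BBox(10, 10, 40, 50, label=1)
        bottom = BBox(25, 10, 60, 50, label=2)
        out = postprocess_boxes(DetectionSet(boxes=(top, bottom)), self.CFG)
        assert len(out) == 1
        assert out.boxes[0].row0 == 10 and out.boxes[0].row1 == 60


class TestDetectCells:
    PRE = PreprocessConfig(rolling_ball_radius_px=30)
    DET = DetectConfig(min_area_px=100)

    def test_blank_image_gives_no_detections(self):
        dets = detect_cells(Image2D(np.zeros((128, 128))), self.PRE, self.DET)
        assert len(dets) == 0

    def test_detection_is_deterministic(self):
        from irf_cellfinder.simulate import SimConfig, add_background_and_noise, render_section, sample_volume

        cfg = SimConfig(volume_shape_px=(40, 256, 256), n_cells=4, noise_sigma=20.0, seed=3)
        sec = add_background_and_noise(render_section(sample_volume(cfg), 20), cfg)
        a = detect_cells(sec.image, self.PRE, self.DET)
        b = detect_cells(sec.image, self.PRE, self.DET)
        assert a.boxes == b.boxes

    def test_five_clean_cells_all_found(self):
        """A noise-free section of five well-separated cells yields exactly
        five detections, each with Dice > 0.5 against its ground truth."""
        from irf_cellfinder.evaluate import dice
        from irf_cellfinder.simulate import Cell, SimConfig, add_background_and_noise, render_section, SimVolume

        cfg = SimConfig(volume_shape_px=(60, 512, 512), noise_sigma=0.0, bg_amplitude=80.0, seed=0)
        z_um = (30 + 0.5) * cfg.slice_thickness_nm / 1000.0
        centers = [(15, 15), (15, 60), (45, 30), (70, 70), (75, 18)]  # um, well separated
        cells = tuple(
            Cell(center_um=(z_um + dz, cy, cx), radius_um=6.0, brightness=120.0)
            for (cy, cx), dz in zip(centers, (0.0, 1.0, -2.0, 0.5, -1.0))
        )
        vol = SimVolume(cells=cells, config=cfg)
        sec = add_background_and_noise(render_section(vol, 30), cfg)
        dets = detect_cells(sec.image, PreprocessConfig(), DetectConfig())
        assert len(dets) == 5
        for g in sec.gt.boxes:
            assert max(dice(d, g) for d in dets.boxes) > 0.5
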
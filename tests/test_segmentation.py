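import numpy as np
import pytest

from trenchph import detect_trenches, make_cohort, render_stack, segment_cells
from trenchph.segmentation import SaturationError

from conftest import pure_fate_preset


@pytest.fixture(scope="module")
def twelve_trench_frame(parental, default_optics):
    preset = pure_fate_preset(parental, "vbnc")
    cohort = make_cohort(preset, 12, seed=1)
    stack = render_stack(cohort, default_optics, mode="image", seed=2)[0]
    return stack, cohort


class TestDetectTrenches:
    def test_twelve_trenches_at_ground_truth(self, twelve_trench_frame):
        stack, _ = twelve_trench_frame
        tmap = detect_trenches(stack.tritc[0])
        truth = stack.trench_rects()
        assert len(tmap) == 12
        for (r0, r1, c0, c1), (tr0, tr1, tc0, tc1) in zip(tmap.rects, truth):
            assert abs(c0 - tc0) <= 1 and abs(c1 - tc1) <= 1
            assert abs(r0 - tr0) <= 1 and abs(r1 - tr1) <= 1

    def test_pitch_matches_optics(self, twelve_trench_frame, default_optics):
        stack, _ = twelve_trench_frame
        tmap = detect_trenches(stack.tritc[0])
        centers = [(c0 + c1) / 2 for _, _, c0, c1 in tmap.rects]
        pitch_px = np.median(np.diff(centers))
        expected = default_optics.trench_pitch_um * default_optics.pixels_per_micron
        assert pitch_px == pytest.approx(expected, abs=1.0)

    def test_blank_frame_empty_map(self):
        rng = np.random.default_rng(0)
        blank = rng.normal(100.0, 10.0, size=(140, 400))
        assert len(detect_trenches(blank)) == 0
        assert len(detect_trenches(np.full((140, 400), 100.0))) == 0

    def test_transposed_frame_same_trenches(self, twelve_trench_frame):
        stack, _ = twelve_trench_frame
        native = detect_trenches(stack.tritc[0])
        flipped = detect_trenches(stack.tritc[0].T)
        assert len(flipped) == len(native)
        swapped = sorted((c0, c1, r0, r1) for r0, r1, c0, c1 in flipped.rects)
        assert swapped == sorted(native.rects)

    def test_rects_disjoint(self, twelve_trench_frame):
        stack, _ = twelve_trench_frame
        tmap = detect_trenches(stack.tritc[0])
        cols = sorted((c0, c1) for _, _, c0, c1 in tmap.rects)
        for (a0, a1), (b0, b1) in zip(cols, cols[1:]):
            assert a1 <= b0


class TestSegmentCells:
    def test_three_cells_recovered(self, parental, default_optics):
        """Three separated synthetic cells in a trench give three masks
        with centroids within a pixel of the ground truth."""
        preset = pure_fate_preset(parental, "persister")
        cohort = make_cohort(preset, 1, seed=12)
        lin = cohort.lineages[0]
        idx24 = len(cohort.schedule_h) - 1
        n_cells = len(lin.cells_per_frame[idx24])
        stack = render_stack(cohort, default_optics, mode="image", seed=3)[0]
        tmap = detect_trenches(stack.tritc[0])
        trench = tmap.extract(stack.tritc[idx24], 0)
        masks = segment_cells(trench, default_optics.pixels_per_micron)
        assert len(masks) == n_cells
        ppm = default_optics.pixels_per_micron
        for mask, geom in zip(masks, lin.cells_per_frame[idx24]):
            assert mask.centroid[0] / ppm == pytest.approx(
                geom.centroid_um, abs=1.5 / ppm)

    def test_empty_trench_zero_masks(self):
        rng = np.random.default_rng(1)
        trench = rng.normal(100.0, 10.0, size=(120, 10))
        assert segment_cells(trench, 6.0) == []
        assert segment_cells(np.full((120, 10), 100.0), 6.0) == []

    def test_speck_removed_by_size_filter(self):
        trench = np.full((120, 10), 100.0)
        trench[20:40, 2:8] = 700.0          # a real cell
        trench[100, 5] = 700.0              # single-pixel noise speck
        masks = segment_cells(trench, 6.0)
        assert len(masks) == 1
        assert masks[0].area_px == pytest.approx(20 * 6, abs=5)

    def test_touching_cells_split_by_watershed(self):
        """A component much longer than the median cell (a division
        doublet) is split into two masks."""
        trench = np.full((120, 12), 100.0)
        trench[10:28, 3:9] = 700.0                    # single cell, 18 px
        trench[34:52, 3:9] = 700.0                    # single cell, 18 px
        trench[60:100, 3:9] = 700.0                   # doublet, 40 px
        masks = segment_cells(trench, 6.0)
        assert len(masks) == 4

    def test_labels_ordered_from_closed_end(self):
        trench = np.full((120, 10), 100.0)
        trench[70:88, 2:8] = 700.0
        trench[10:28, 2:8] = 700.0
        masks = segment_cells(trench, 6.0)
        assert [m.label for m in masks] == [1, 2]
        assert masks[0].centroid[0] < masks[1].centroid[0]

    def test_masks_disjoint(self, twelve_trench_frame, default_optics):
        stack, _ = twelve_trench_frame
        tmap = detect_trenches(stack.tritc[0])
        trench = tmap.extract(stack.tritc[0], 0)
        masks = segment_cells(trench, default_optics.pixels_per_micron)
        seen = set()
        for m in masks:
            ids = m.pixel_ids()
            assert not ids & seen
            seen |= ids

    @pytest.mark.parametrize("min_area", [0.2, 0.5, 1.0, 3.0, 10.0])
    def test_count_monotone_in_size_filter(self, min_area):
        trench = np.full((120, 10), 100.0)
        trench[10:28, 2:8] = 700.0
        trench[50:54, 3:6] = 700.0          # small object ~0.3 um^2 at 6 ppm
        counts = [len(segment_cells(trench, 6.0, min_area_um2=a))
                  for a in (0.05, min_area)]
        assert counts[1] <= counts[0]

    def test_saturated_raster_errors(self):
        trench = np.full((120, 10), 65535, dtype=np.uint16)
        with pytest.raises(SaturationError, match="bit depth"):
            segment_cells(trench, 6.0)


def test_noiseless_detection_perfect(parental, noiseless_optics):
    """On noiseless renders, every true cell is found and nothing else
    (recall = precision = 1)."""
    preset = pure_fate_preset(parental, "vbnc")
    cohort = make_cohort(preset, 10, seed=21)
    stack = render_stack(cohort, noiseless_optics, mode="image", seed=0)[0]
    tmap = detect_trenches(stack.tritc[0])
    assert len(tmap) == 10
    for k, lin in enumerate(cohort.lineages):
        for f in range(len(cohort.schedule_h)):
            trench = tmap.extract(stack.tritc[f], k)
            masks = segment_cells(trench, noiseless_optics.pixels_per_micron)
            assert len(masks) == len(lin.cells_per_frame[f])
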
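import numpy as np
import pytest

from trenchph import build_lineages, link_frames, make_cohort, render_stack
from trenchph.segmentation import CellMask, detect_trenches, segment_cells

from conftest import pure_fate_preset

SHAPE = (120, 10)
PPM = 6.0


def make_mask(r0, r1, label, c0=2, c1=8, shape=SHAPE):
    """Rectangular CellMask spanning rows [r0, r1) in a trench raster."""
    arr = np.zeros(shape, dtype=bool)
    arr[r0:r1, c0:c1] = True
    pixels = np.argwhere(arr)
    return CellMask(
        label=label, pixels=pixels, trench_shape=shape,
        centroid=tuple(pixels.mean(axis=0)),
        length_um=(r1 - r0) / PPM, width_um=(c1 - c0) / PPM,
        area_um2=len(pixels) / PPM ** 2)


class TestLinkFrames:
    def test_continuation(self):
        link = link_frames([make_mask(10, 28, 1)], [make_mask(10, 32, 1)])
        assert link.children[1] == (1,)

    def test_division_parent_tiled_by_daughters(self):
        parent = make_mask(10, 46, 1)
        d1, d2 = make_mask(10, 26, 1), make_mask(29, 46, 2)
        link = link_frames([parent], [d1, d2])
        assert set(link.children[1]) == {1, 2}

    def test_disappearance(self):
        link = link_frames([make_mask(10, 28, 1)], [])
        assert link.children[1] == ()

    def test_washed_in_near_open_end(self):
        link = link_frames([make_mask(10, 28, 1)],
                           [make_mask(10, 28, 1), make_mask(100, 118, 2)])
        assert link.washed_in == {2}

    def test_label_permutation_invariance(self):
        parent = make_mask(10, 46, 1)
        d1, d2 = make_mask(10, 26, 7), make_mask(29, 46, 3)
        a = link_frames([parent], [d1, d2])
        b = link_frames([parent], [d2, d1])
        assert set(a.children[1]) == set(b.children[1]) == {7, 3}

    def test_empty_inputs_allowed(self):
        link = link_frames([], [])
        assert link.children == {} and not link.washed_in


class TestBuildLineages:
    TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 24.0)

    def test_single_cell_full_movie(self):
        frames = [[make_mask(10, 28, 1)] for _ in self.TIMES]
        result = build_lineages(frames, self.TIMES)
        assert len(result.lineages) == 1
        lin = result.lineages[0]
        assert all(lin.alive_at(i) for i in range(len(self.TIMES)))
        assert lin.events[-1] == (24.0, "end_of_movie")
        assert result.washed_in == 0

    def test_division_event_recorded(self):
        frames = ([[make_mask(10, 28, 1)]] * 5
                  + [[make_mask(10, 46, 1)]]           # elongated at 4 h... 5 h
                  + [[make_mask(10, 26, 1), make_mask(29, 46, 2)]] * 2)
        result = build_lineages(frames, self.TIMES)
        lin = result.lineages[0]
        assert (6.0, "division") in lin.events
        assert lin.count_at(7) == 2
        assert lin.divided_after(3.0, self.TIMES)

    def test_disappearance_time_recorded(self):
        frames = ([[make_mask(10, 28, 1)]] * 2 + [[]] * 6)
        result = build_lineages(frames, self.TIMES)
        lin = result.lineages[0]
        assert (2.0, "disappearance") in lin.events
        assert not lin.alive_at(7)

    def test_single_frame_gap_bridged(self):
        frames = [[make_mask(10, 28, 1)] for _ in self.TIMES]
        frames[3] = []                       # one missed detection
        result = build_lineages(frames, self.TIMES)
        lin = result.lineages[0]
        assert not any(kind == "disappearance" for _, kind in lin.events)
        assert lin.alive_at(7)

    def test_conservation(self):
        frames = ([[make_mask(10, 28, 1)]] * 6
                  + [[make_mask(10, 28, 1), make_mask(100, 118, 9)]] * 2)
        result = build_lineages(frames, self.TIMES)
        total = sum(len(f) for f in frames)
        assigned = sum(len(m) for lin in result.lineages
                       for m in lin.masks_by_frame.values())
        assert assigned + result.washed_in == total

    def test_regrowth_between_6_and_24_counts_as_division(self):
        """A net cell-count increase at 24 h connected to the resident is
        division evidence even though no intermediate frame shows it."""
        frames = ([[make_mask(10, 28, 1)]] * 7
                  + [[make_mask(10, 28, 1), make_mask(33, 51, 2)]])
        result = build_lineages(frames, self.TIMES)
        lin = result.lineages[0]
        assert lin.divided_after(3.0, self.TIMES)


class TestOnSyntheticCohorts:
    def _track(self, cohort, optics, seed=0):
        stack = render_stack(cohort, optics, mode="image", seed=seed)[0]
        tmap = detect_trenches(stack.tritc[0])
        out = []
        for k in range(len(tmap)):
            masks_per_frame = [
                segment_cells(tmap.extract(stack.tritc[f], k),
                              optics.pixels_per_micron)
                for f in range(len(cohort.schedule_h))]
            out.append(build_lineages(masks_per_frame, cohort.schedule_h,
                                      trench_id=k))
        return out

    def test_division_and_lysis_recovered_on_frame_grid(
            self, parental, noiseless_optics):
        """On noiseless renders, divisions and lysis land on the first
        scheduled frame after the true event time."""
        times = np.array((0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 24.0))
        pers = make_cohort(pure_fate_preset(parental, "persister"), 6, seed=3)
        for tid, res in enumerate(self._track(pers, noiseless_optics)):
            lin = res.lineages[0]
            truth = pers.lineages[tid]
            expected = sorted(set(
                float(times[np.searchsorted(times, d)])
                for d in truth.division_times if d <= 24.0))
            assert sorted(set(lin.division_times())) == expected

        sus = make_cohort(pure_fate_preset(parental, "susceptible"), 8, seed=4)
        for tid, res in enumerate(self._track(sus, noiseless_optics)):
            lin = res.lineages[0]
            truth = sus.lineages[tid]
            if truth.lysis_time is None:
                assert lin.alive_at(7)
                continue
            expected = float(times[np.searchsorted(times, truth.lysis_time)])
            assert lin.disappearance_time() == expected
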
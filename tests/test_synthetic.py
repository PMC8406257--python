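import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from trenchph import (OpticsConfig, apply_pi_event, make_cohort,
                      render_calibration_set, render_stack)
from trenchph.pipeline import photometer_frame
from trenchph.presets import PresetError
from trenchph.synthetic import GenerationError

from conftest import pure_fate_preset


class TestMakeCohort:
    def test_seeded_determinism(self, parental):
        a = make_cohort(parental, 10, seed=7)
        b = make_cohort(parental, 10, seed=7)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        for la, lb in zip(a.lineages, b.lineages):
            assert la.division_times == lb.division_times
            assert la.lysis_time == lb.lysis_time
            assert la.cells_per_frame == lb.cells_per_frame

    def test_degenerate_probs_all_persister(self, parental):
        pure = pure_fate_preset(parental, "persister")
        cohort = make_cohort(pure, 50, seed=3)
        for lin in cohort.lineages:
            assert lin.fate == "persister"
            assert len(lin.division_times) >= 1
            assert all(3.0 < d <= 24.0 for d in lin.division_times)

    def test_fate_invariants(self, parental):
        cohort = make_cohort(parental, 400, seed=5)
        for lin in cohort.lineages:
            if lin.fate == "vbnc":
                assert not lin.division_times and not lin.pi_positive
            if lin.fate == "susceptible_lysed":
                assert lin.lysis_time is not None
                # true pH defined at every frame before lysis
                for k, t in enumerate(cohort.schedule_h):
                    if t < lin.lysis_time:
                        assert np.isfinite(lin.true_ph[k])
            if lin.fate == "persister":
                assert lin.division_times

    def test_fate_frequencies_converge(self, parental):
        """Large-cohort fate frequencies agree with the preset: the
        persister rate sits within 3 binomial SDs of 0.01 and a chi-square
        goodness-of-fit test does not reject at alpha=0.01."""
        n = 100_000
        cohort = make_cohort(parental, n, seed=11)
        counts = cohort.fate_counts()
        p_pers = counts.get("persister", 0) / n
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(p_pers - 0.01) < 3 * se
        observed = [counts.get("persister", 0), counts.get("vbnc", 0),
                    counts.get("susceptible_lysed", 0)
                    + counts.get("susceptible_not_lysed", 0)]
        expected = [n * p for p in parental.fate_probs]
        stat, p = sstats.chisquare(observed, expected)
        assert p > 0.01

    def test_invalid_preset_raises_named_error(self, parental):
        bad = dataclasses.replace(parental, fate_probs=(0.5, 0.4, 0.0))
        with pytest.raises(PresetError, match="fate_probs"):
            make_cohort(bad, 5, seed=0)


class TestRenderStack:
    def test_noiseless_ratio_matches_truth(self, parental, noiseless_optics):
        """After background removal, the measured per-cell ratio equals
        the ground-truth map applied to the true pH (raster quantization
        below 0.5 %)."""
        cohort = make_cohort(pure_fate_preset(parental, "vbnc"), 8, seed=2)
        stacks = render_stack(cohort, noiseless_optics, mode="image", seed=1)
        records = photometer_frame(stacks[0], frame_idx=0)
        assert len(records) == 8
        for rec in records:
            truth = cohort.lineages[rec.lineage_id]
            expect = float(noiseless_optics.ratio_for_ph(truth.true_ph[0]))
            assert rec.ratio == pytest.approx(expect, rel=5e-3)

    def test_expression_scaling_cancels_in_ratio(self, parental,
                                                 noiseless_optics):
        """Doubling a cell's expression doubles both channels but leaves
        the rendered ratio unchanged."""
        cohort = make_cohort(pure_fate_preset(parental, "vbnc"), 1, seed=4)
        doubled = dataclasses.replace(
            cohort, lineages=(dataclasses.replace(
                cohort.lineages[0],
                expression=2 * cohort.lineages[0].expression),))
        rec1 = photometer_frame(
            render_stack(cohort, noiseless_optics, "image", 0)[0], 0)[0]
        rec2 = photometer_frame(
            render_stack(doubled, noiseless_optics, "image", 0)[0], 0)[0]
        assert rec2.i_fitc == pytest.approx(2 * rec1.i_fitc, rel=1e-2)
        assert rec2.i_tritc == pytest.approx(2 * rec1.i_tritc, rel=1e-2)
        assert rec2.ratio == pytest.approx(rec1.ratio, rel=1e-3)

    def test_expression_scaling_exact_in_traces(self, parental,
                                                noiseless_optics):
        """In trace mode the common-mode cancellation is algebraic."""
        cohort = make_cohort(pure_fate_preset(parental, "vbnc"), 1, seed=4)
        doubled = dataclasses.replace(
            cohort, lineages=(dataclasses.replace(
                cohort.lineages[0],
                expression=2 * cohort.lineages[0].expression),))
        t1 = render_stack(cohort, noiseless_optics, "trace", 0)
        t2 = render_stack(doubled, noiseless_optics, "trace", 0)
        np.testing.assert_allclose(t2.tritc, 2 * t1.tritc, rtol=1e-12)
        np.testing.assert_allclose(t2.fitc / t2.tritc, t1.fitc / t1.tritc,
                                   rtol=1e-12)

    def test_trace_vs_image_photometry_agree(self, parental, default_optics,
                                             exact_model):
        """Per-cell t=0 ratios measured on rendered images agree with the
        noiseless-equivalent traces to within the propagated noise."""
        cohort = make_cohort(pure_fate_preset(parental, "vbnc"), 12, seed=6)
        traces = render_stack(cohort, default_optics, mode="trace", seed=7)
        t0 = traces[(traces.frame_h == 0.0) & (traces.cell_slot == 0)]
        trace_ratio = (t0.fitc / t0.tritc).to_numpy()
        stack = render_stack(cohort, default_optics, mode="image", seed=7)[0]
        recs = {r.lineage_id: r for r in photometer_frame(stack, 0)}
        img_ratio = np.array([recs[tid].ratio for tid in t0.trench_id])
        # noise SD of the per-cell mean-based ratio is well below 0.01
        assert np.all(np.abs(img_ratio - trace_ratio) < 3 * 0.01)

    def test_lysed_cells_disappear(self, parental, noiseless_optics):
        cohort = make_cohort(pure_fate_preset(parental, "susceptible"),
                             20, seed=8)
        lysed = [lin for lin in cohort.lineages
                 if lin.fate == "susceptible_lysed"]
        assert lysed
        traces = render_stack(cohort, noiseless_optics, mode="trace", seed=0)
        for lin in lysed:
            after = traces[(traces.trench_id == lin.trench_id)
                           & (traces.frame_h >= lin.lysis_time)]
            assert after.empty

    def test_capacity_error(self, parental, noiseless_optics):
        cohort = make_cohort(parental, 1, seed=0)
        big = dataclasses.replace(cohort.lineages[0], cells_per_frame=tuple(
            tuple(dataclasses.replace(c, length_um=25.0) for c in frame)
            for frame in cohort.lineages[0].cells_per_frame))
        bad = dataclasses.replace(cohort, lineages=(big,))
        with pytest.raises(GenerationError, match="capacity"):
            render_stack(bad, noiseless_optics, mode="image", seed=0)


class TestCalibrationSet:
    def test_four_standards_increasing_ratios(self, default_optics):
        standards = [6.5, 7.0, 7.5, 8.0]
        stacks = render_calibration_set(standards, default_optics, seed=1)
        assert len(stacks) == 4
        means = []
        for stack in stacks:
            recs = photometer_frame(stack, 0)
            means.append(np.mean([r.ratio for r in recs if r.ratio_defined]))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_noiseless_ratios_on_truth_line(self, noiseless_optics):
        """With noise and blur off the measured ratios sit exactly on the
        ground-truth line; with realistic blur they stay within 0.5 %."""
        sharp = noiseless_optics.replace(psf_sigma_um=1e-9)
        recs = photometer_frame(
            render_calibration_set([7.0], sharp, seed=1)[0], 0)
        for rec in recs:
            assert rec.ratio == pytest.approx(0.6, abs=1e-9)
        recs = photometer_frame(
            render_calibration_set([7.0], noiseless_optics, seed=1)[0], 0)
        for rec in recs:
            assert rec.ratio == pytest.approx(0.6, rel=5e-3)

    def test_noisy_within_stack_sd_small(self, default_optics):
        """Per-cell ratio spread in one standard's stack is consistent
        with the shot/read-noise model (mean over ~100 px cancels most)."""
        stacks = render_calibration_set([7.5], default_optics, seed=2,
                                        n_cells=40)
        recs = photometer_frame(stacks[0], 0)
        ratios = np.array([r.ratio for r in recs if r.ratio_defined])
        assert ratios.std() < 0.01
        assert abs(ratios.mean() - 0.7) < 0.005

    def test_empty_standards_error(self, default_optics):
        with pytest.raises(ValueError, match="at least one"):
            render_calibration_set([], default_optics, seed=0)


class TestPiEvent:
    def test_fold_changes_by_fate(self, parental, noiseless_optics):
        cohort = make_cohort(parental, 60, seed=9)
        traces = render_stack(cohort, noiseless_optics, mode="trace", seed=0)
        traces = apply_pi_event(cohort, traces, optics=noiseless_optics)
        post = traces[traces.phase == "post_pi"].set_index(
            ["trench_id", "cell_slot"])
        pre = traces[(traces.phase == "timelapse")
                     & (traces.frame_h == 24.0)].set_index(
            ["trench_id", "cell_slot"])
        for lin in cohort.lineages:
            key = (lin.trench_id, 0)
            if lin.fate == "susceptible_lysed":
                assert key not in post.index
                continue
            fold = post.loc[key, "tritc"] / pre.loc[key, "tritc"]
            expect = 3.0 if lin.fate == "susceptible_not_lysed" else 1.0
            assert fold == pytest.approx(expect, rel=1e-9)

    def test_missing_24h_frame_error(self, parental, noiseless_optics):
        cohort = make_cohort(parental, 3, seed=1)
        traces = render_stack(cohort, noiseless_optics, mode="trace", seed=0)
        truncated = traces[traces.frame_h < 24.0]
        with pytest.raises(ValueError, match="24 h"):
            apply_pi_event(cohort, truncated, optics=noiseless_optics)
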
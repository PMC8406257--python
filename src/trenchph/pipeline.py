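"""End-to-end orchestration: generate -> segment -> track -> photometer ->
calibrate -> phenotype -> summarize.

The experiment timeline mirrors the assay: cells are imaged before
treatment (t = 0), hourly during 3 h of ampicillin at 25x MIC and the
first hours of drug-free regrowth, and at 24 h, when propidium iodide is
flushed through the device and one extra red frame is taken.  The
analysis never reads ground-truth fields; :func:`evaluate` joins calls to
truth separately for confusion matrices.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (CalibrationModel, calibration_points_from_stacks,
                          fit_calibration)
from .phenotyping import LineageEvidence, classify_cohort
from .photometry import estimate_background, measure_cell
from .presets import IMAGING_SCHEDULE_H, PresetError, StrainPreset, load_preset
from .segmentation import detect_trenches, segment_cells
from .stats import phenotype_fractions, ph_distribution
from .synthetic import (CohortGroundTruth, FrameStack, OpticsConfig,
                        apply_pi_event, make_cohort, render_calibration_set,
                        render_stack)
from .tracking import build_lineages

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "ExperimentResult", "PipelineError",
           "photometer_frame", "run_calibration", "analyze_stacks",
           "analyze_traces", "run_experiment", "evaluate", "summarize_ph"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully explicit, serializable description of one pipeline run."""

    preset: str = "parental"
    n_lineages: int = 500
    mode: str = "trace"                   # "trace" or "image"
    seed: int = 0
    cohort_seed: int | None = None
    render_seed: int | None = None
    calibration_seed: int | None = None
    calibration_standards: tuple[float, ...] = (6.5, 7.0, 7.5, 8.0)
    calibration_noiseless: bool = False
    pi_fold_threshold: float = 2.0
    low_expression_percentile: float = 10.0
    low_signal_floor: float = 10.0
    min_cell_area_um2: float = 0.5
    optics: dict = field(default_factory=dict)
    outdir: str = "trenchph_out"

    def validate(self) -> None:
        if self.n_lineages < 1:
            raise PresetError("n_lineages: must be >= 1")
        if self.mode not in ("trace", "image"):
            raise PresetError("mode: must be 'trace' or 'image'")
        if not 1.0 < self.pi_fold_threshold <= 10.0:
            raise PresetError("pi_fold_threshold: must be in (1, 10]")
        if not 0.0 <= self.low_expression_percentile <= 50.0:
            raise PresetError("low_expression_percentile: must be in [0, 50]")
        if len(self.calibration_standards) < 2:
            raise PresetError("calibration_standards: need >= 2 standards")

    def resolved_seeds(self) -> tuple[int, int, int]:
        """(cohort, render, calibration) seeds; unspecified ones are
        derived deterministically from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        derived = [int(c.generate_state(1)[0] % (2 ** 31))
                   for c in ss.spawn(3)]
        return (
            self.cohort_seed if self.cohort_seed is not None else derived[0],
            self.render_seed if self.render_seed is not None else derived[1],
            self.calibration_seed if self.calibration_seed is not None
            else derived[2],
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["calibration_standards"] = list(self.calibration_standards)
        cs, rs, ks = self.resolved_seeds()
        d["resolved_seeds"] = {"cohort": cs, "render": rs, "calibration": ks}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.pop("resolved_seeds", None)
        if "calibration_standards" in d:
            d["calibration_standards"] = tuple(d["calibration_standards"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def photometer_frame(stack: FrameStack, frame_idx: int,
                     min_area_um2: float = 0.5,
                     low_signal_floor: float = 10.0):
    """Detect trenches, segment and photometer one frame of a stack;
    returns the per-cell :class:`~trenchph.photometry.PhotometryRecord` list."""
    tritc = stack.tritc[frame_idx]
    fitc = stack.fitc[frame_idx]
    tmap = detect_trenches(tritc)
    ppm = stack.optics.pixels_per_micron
    records = []
    for k in range(len(tmap)):
        tr_t = tmap.extract(tritc, k)
        tr_f = tmap.extract(fitc, k)
        masks = segment_cells(tr_t, ppm, min_area_um2=min_area_um2,
                              trench_id=k, frame_h=stack.times_h[frame_idx])
        if not masks:
            continue
        b_f, b_t = estimate_background(tr_f, tr_t, masks)
        for m in masks:
            records.append(measure_cell(m, tr_f, tr_t, b_f, b_t,
                                        low_signal_floor, lineage_id=k))
    return records


def run_calibration(optics: OpticsConfig | None = None,
                    standards=(6.5, 7.0, 7.5, 8.0),
                    seed: int = 0, n_cells: int = 24,
                    min_area_um2: float = 0.5) -> CalibrationModel:
    """Render protonophore-equilibrated standards and fit the curve."""
    optics = optics or OpticsConfig()
    stacks = render_calibration_set(list(standards), optics, seed=seed,
                                    n_cells=n_cells)
    points = calibration_points_from_stacks(stacks, list(standards),
                                            min_area_um2=min_area_um2)
    model = fit_calibration(points)
    log.info("calibration fitted:\n%s", model.summary())
    return model


@dataclass
class AnalysisResult:
    """Per-cell photometry with pH estimates plus per-lineage calls."""

    photometry: pd.DataFrame   # lineage_id, frame_h, i_fitc, i_tritc, ratio, ph, ph_valid
    calls: pd.DataFrame        # lineage_id, label, evidence columns
    model: CalibrationModel


def _attach_ph(df: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    ph, valid = model.ratio_to_ph(df["ratio"].to_numpy())
    df = df.copy()
    df["ph"] = ph
    df["ph_valid"] = valid
    return df


def _calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([{
        "lineage_id": c.lineage_id, "label": c.label,
        "divided_after_3h": c.divided_after_3h,
        "present_at_24h": c.present_at_24h,
        "pi_fold": c.pi_fold,
        "expression_percentile": c.expression_percentile,
    } for c in calls])


def analyze_stacks(stacks: list[FrameStack], model: CalibrationModel,
                   min_area_um2: float = 0.5,
                   pi_fold_threshold: float = 2.0,
                   low_expression_percentile: float = 10.0,
                   low_signal_floor: float = 10.0) -> AnalysisResult:
    """Full image-mode analysis of rendered (or re-loaded) stacks.

    Each field of view is processed trench by trench: segmentation on the
    TRITC channel, overlap tracking into lineages, per-frame photometry of
    the mother (closed-end) cell, PI response from the post-stain frame,
    then cohort-level classification.
    """
    rows = []
    evidences = []
    for stack in stacks:
        times = stack.times_h
        if 24.0 not in times:
            raise PipelineError("analyze", "stack lacks the 24 h frame")
        idx24 = times.index(24.0)
        tmap = detect_trenches(stack.tritc[0])
        if len(tmap) != len(stack.trench_ids):
            log.warning("analyze: detected %d trenches, expected %d",
                        len(tmap), len(stack.trench_ids))
        ppm = stack.optics.pixels_per_micron
        for k in range(min(len(tmap), len(stack.trench_ids))):
            tid = stack.trench_ids[k]
            masks_per_frame = []
            crops = []
            for f, t in enumerate(times):
                tr_t = tmap.extract(stack.tritc[f], k)
                tr_f = tmap.extract(stack.fitc[f], k)
                crops.append((tr_f, tr_t))
                masks_per_frame.append(
                    segment_cells(tr_t, ppm, min_area_um2=min_area_um2,
                                  trench_id=tid, frame_h=t))
            tracking = build_lineages(masks_per_frame, times, trench_id=tid)
            roots = [lin for lin in tracking.lineages if lin.alive_at(0)]
            if not roots:
                continue
            if len(roots) > 1:
                log.warning("trench %d: %d cells at t=0; keeping the mother "
                            "(closed end) only", tid, len(roots))
            lin = roots[0]

            per_frame = {}
            for f, t in enumerate(times):
                mask = lin.mother_mask(f)
                if mask is None:
                    continue
                tr_f, tr_t = crops[f]
                b_f, b_t = estimate_background(tr_f, tr_t, masks_per_frame[f])
                rec = measure_cell(mask, tr_f, tr_t, b_f, b_t,
                                   low_signal_floor, lineage_id=tid)
                per_frame[f] = rec
                rows.append({
                    "lineage_id": tid, "frame_h": t,
                    "i_fitc": rec.i_fitc, "i_tritc": rec.i_tritc,
                    "b_fitc": rec.b_fitc, "b_tritc": rec.b_tritc,
                    "ratio": rec.ratio, "flags": ";".join(rec.flags),
                })

            present_24 = lin.alive_at(idx24)
            post_pi = float("nan")
            pi_available = stack.tritc_post_pi is not None
            if present_24 and pi_available:
                mask24 = lin.mother_mask(idx24)
                tr_post = tmap.extract(stack.tritc_post_pi, k)
                _, b_post = estimate_background(
                    tr_post, tr_post, masks_per_frame[idx24])
                rec_post = measure_cell(mask24, tr_post, tr_post,
                                        b_post, b_post, low_signal_floor)
                post_pi = rec_post.i_tritc
            evidences.append(LineageEvidence(
                lineage_id=tid,
                present_at_24h=present_24,
                divided_after_3h=lin.divided_after(3.0, times),
                t0_tritc=per_frame[0].i_tritc if 0 in per_frame else float("nan"),
                tritc_24h=per_frame[idx24].i_tritc if idx24 in per_frame
                else float("nan"),
                post_pi_tritc=post_pi,
                pi_frame_available=pi_available))

    photometry = _attach_ph(pd.DataFrame(rows), model)
    calls = classify_cohort(evidences, low_expression_percentile,
                            pi_fold_threshold, low_signal_floor)
    return AnalysisResult(photometry=photometry, calls=_calls_frame(calls),
                          model=model)


def analyze_traces(traces: pd.DataFrame, model: CalibrationModel,
                   pi_fold_threshold: float = 2.0,
                   low_expression_percentile: float = 10.0,
                   low_signal_floor: float = 10.0) -> AnalysisResult:
    """Trace-mode analysis: the per-cell intensities skip the raster, but
    lineage logic (presence, division evidence, PI response) and the
    classification are identical to image mode."""
    tl = traces[traces["phase"] == "timelapse"]
    post = traces[traces["phase"] == "post_pi"]
    post_mother = post[post["cell_slot"] == 0].set_index("trench_id")["tritc"]
    pi_available = len(post) > 0

    rows = []
    evidences = []
    for tid, g in tl.groupby("trench_id"):
        counts = g.groupby("frame_h").size()
        if counts.get(0.0, 0) == 0:
            continue  # no t=0 resident: excluded from downstream analysis
        mother = g[g["cell_slot"] == 0].set_index("frame_h")
        for t, rec in mother.iterrows():
            ratio = rec["fitc"] / rec["tritc"] if rec["tritc"] > 0 else float("nan")
            rows.append({
                "lineage_id": tid, "frame_h": t,
                "i_fitc": rec["fitc"], "i_tritc": rec["tritc"],
                "b_fitc": 0.0, "b_tritc": 0.0,
                "ratio": ratio, "flags": "",
            })
        ref = counts.get(3.0, counts.get(0.0, 1))
        divided = bool(any(counts.get(t, 0) > ref
                           for t in counts.index if t > 3.0))
        present_24 = counts.get(24.0, 0) > 0
        evidences.append(LineageEvidence(
            lineage_id=int(tid),
            present_at_24h=bool(present_24),
            divided_after_3h=divided,
            t0_tritc=float(mother.loc[0.0, "tritc"]),
            tritc_24h=float(mother.loc[24.0, "tritc"])
            if present_24 else float("nan"),
            post_pi_tritc=float(post_mother.get(tid, float("nan"))),
            pi_frame_available=pi_available))

    photometry = _attach_ph(pd.DataFrame(rows), model)
    calls = classify_cohort(evidences, low_expression_percentile,
                            pi_fold_threshold, low_signal_floor)
    return AnalysisResult(photometry=photometry, calls=_calls_frame(calls),
                          model=model)


# ---------------------------------------------------------------------------
# Summaries, evaluation, full runs
# ---------------------------------------------------------------------------

def summarize_ph(result: AnalysisResult,
                 combine_susceptible: bool = True) -> pd.DataFrame:
    """Per-phenotype, per-time mean +/- SEM of valid pH estimates."""
    df = result.photometry.merge(result.calls[["lineage_id", "label"]],
                                 on="lineage_id")
    if combine_susceptible:
        df["label"] = df["label"].replace({
            "susceptible_lysed": "susceptible",
            "susceptible_not_lysed": "susceptible"})
    rows = []
    for (label, t), g in df.groupby(["label", "frame_h"]):
        vals = g.loc[g["ph_valid"], "ph"].to_numpy()
        summ = ph_distribution(vals, phenotype=label, time_h=t,
                               detect_modes_min_n=10 ** 9)
        rows.append({"label": label, "frame_h": t, "mean_ph": summ.mean,
                     "sem": summ.sem, "n": summ.n,
                     "n_excluded": summ.n_excluded})
    return pd.DataFrame(rows).sort_values(["label", "frame_h"],
                                          ignore_index=True)


def evaluate(calls: pd.DataFrame, cohort: CohortGroundTruth) -> pd.DataFrame:
    """Confusion matrix of phenotype calls against ground-truth fates."""
    truth = pd.DataFrame({
        "lineage_id": [lin.lineage_id for lin in cohort.lineages],
        "fate": [lin.fate for lin in cohort.lineages]})
    joined = calls.merge(truth, on="lineage_id", how="inner")
    return pd.crosstab(joined["fate"], joined["label"])


@dataclass
class ExperimentResult:
    config: RunConfig
    cohort: CohortGroundTruth
    model: CalibrationModel
    analysis: AnalysisResult
    summary: pd.DataFrame
    fractions: "object"

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        optics = OpticsConfig().replace(**self.config.optics)
        self.cohort.to_frame(optics).to_csv(out / "ground_truth.csv",
                                            index=False)
        self.analysis.photometry.to_csv(out / "photometry.csv", index=False)
        self.analysis.calls.to_csv(out / "calls.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.model.save(out / "calibration.yaml")
        f = self.fractions
        frac_df = pd.DataFrame([
            {"phenotype": "persister", "fraction": f.f_persister,
             "se": f.se_persister, "n_total": f.n_total},
            {"phenotype": "vbnc", "fraction": f.f_vbnc,
             "se": f.se_vbnc, "n_total": f.n_total},
            {"phenotype": "susceptible", "fraction": f.f_susceptible,
             "se": f.se_susceptible, "n_total": f.n_total},
        ])
        frac_df.to_csv(out / "fractions.csv", index=False)
        (out / "run.log").write_text(
            "# resolved configuration\n" + self.config.to_yaml())


def run_experiment(config: RunConfig,
                   preset: StrainPreset | None = None) -> ExperimentResult:
    """Run the whole pipeline for one cohort under one configuration.

    Deterministic given the resolved config; writes the output bundle to
    ``config.outdir`` (ground truth, photometry, calls, summaries,
    fractions, calibration model, run log).
    """
    config.validate()
    cohort_seed, render_seed, calib_seed = config.resolved_seeds()
    try:
        preset = preset or load_preset(config.preset)
        optics = OpticsConfig().replace(**config.optics)
    except Exception as exc:
        raise PipelineError("config", str(exc)) from exc

    try:
        cohort = make_cohort(preset, config.n_lineages, cohort_seed)
    except Exception as exc:
        raise PipelineError("generate", str(exc)) from exc

    try:
        calib_optics = optics.replace(shot_noise=False, read_noise_sd=0.0) \
            if config.calibration_noiseless else optics
        model = run_calibration(calib_optics, config.calibration_standards,
                                seed=calib_seed,
                                min_area_um2=config.min_cell_area_um2)
    except Exception as exc:
        raise PipelineError("calibrate", str(exc)) from exc

    try:
        if config.mode == "trace":
            traces = render_stack(cohort, optics, mode="trace",
                                  seed=render_seed)
            traces = apply_pi_event(cohort, traces, seed=render_seed,
                                    optics=optics)
            analysis = analyze_traces(
                traces, model,
                pi_fold_threshold=config.pi_fold_threshold,
                low_expression_percentile=config.low_expression_percentile,
                low_signal_floor=config.low_signal_floor)
        else:
            stacks = render_stack(cohort, optics, mode="image",
                                  seed=render_seed)
            for i, stack in enumerate(stacks):
                apply_pi_event(cohort, stack, seed=render_seed + i + 1)
            analysis = analyze_stacks(
                stacks, model,
                min_area_um2=config.min_cell_area_um2,
                pi_fold_threshold=config.pi_fold_threshold,
                low_expression_percentile=config.low_expression_percentile,
                low_signal_floor=config.low_signal_floor)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("analyze", str(exc)) from exc

    try:
        summary = summarize_ph(analysis)
        fractions = phenotype_fractions(analysis.calls["label"].tolist())
    except Exception as exc:
        raise PipelineError("summarize", str(exc)) from exc

    result = ExperimentResult(config=config, cohort=cohort, model=model,
                              analysis=analysis, summary=summary,
                              fractions=fractions)
    if config.outdir:
        result.write(config.outdir)
    return result
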
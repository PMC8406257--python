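"""Ground-truthed synthetic mother-machine scenes.

This module replaces the microscope: it draws cohorts of mother-cell
lineages with known fates and intracellular-pH trajectories from a
:class:`~trenchph.presets.StrainPreset`, and renders them either as
two-channel (FITC = pH reporter, TRITC = expression reporter) image stacks
on a trench raster, or as per-cell noiseless-equivalent intensity traces.

The rendered signal obeys the ratiometric contract: within a cell, the
expected FITC/TRITC per-pixel ratio after background removal equals the
ground-truth ratio map applied to the cell's true pH, and both channels
scale identically with the cell's expression level, so the ratio is immune
to copy-number variability.  Shot noise (Poisson on expected counts) and
Gaussian read noise model an sCMOS detector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .presets import (
    FATES,
    IMAGING_SCHEDULE_H,
    PH_HARD_RANGE,
    PresetError,
    StrainPreset,
)

__all__ = [
    "OpticsConfig",
    "CellGeometry",
    "LineageTruth",
    "CohortGroundTruth",
    "FrameStack",
    "GenerationError",
    "make_cohort",
    "render_stack",
    "render_calibration_set",
    "apply_pi_event",
]


class GenerationError(RuntimeError):
    """Raised when a cohort cannot be rendered onto the trench raster."""


# ---------------------------------------------------------------------------
# Optics / raster configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsConfig:
    """Raster geometry, detector noise and the ground-truth ratio map.

    The ground-truth map is the line ``pH = ph_slope * R + ph_intercept``
    relating the background-free FITC/TRITC ratio ``R`` to true pH; the
    renderer emits ``FITC = R(pH) * TRITC`` pixelwise.  Defaults keep hand
    computations exact (pH = 5 R + 4, so pH 7.5 <-> R = 0.7).
    """

    pixels_per_micron: float = 6.0
    trench_length_um: float = 20.0
    trench_width_um: float = 1.6
    trench_pitch_um: float = 6.0
    trenches_per_fov: int = 12
    margin_um: float = 1.5
    psf_sigma_um: float = 0.15
    background_in_trench: float = 100.0   # medium autofluorescence, counts
    background_outside: float = 60.0      # PDMS, counts
    tritc_counts: float = 600.0           # per unit expression, above bg
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    ph_slope: float = 5.0
    ph_intercept: float = 4.0

    def validate(self) -> None:
        for name in ("pixels_per_micron", "trench_length_um",
                     "trench_width_um", "trench_pitch_um", "margin_um",
                     "tritc_counts"):
            if getattr(self, name) <= 0:
                raise PresetError(f"optics.{name}: must be > 0")
        if self.trench_width_um >= self.trench_pitch_um:
            raise PresetError("optics: trench width must be below the pitch")
        if self.background_in_trench < 0 or self.background_outside < 0:
            raise PresetError("optics: backgrounds must be >= 0")
        if self.read_noise_sd < 0:
            raise PresetError("optics.read_noise_sd: must be >= 0")
        if self.ph_slope <= 0:
            raise PresetError(
                "optics: ratio map must be strictly increasing in pH "
                "(ph_slope > 0)")
        lo, hi = PH_HARD_RANGE
        if self.ratio_for_ph(lo) <= 0:
            raise PresetError(
                f"optics: ratio map must be positive over [{lo}, {hi}]")

    def ratio_for_ph(self, ph):
        """Ground-truth FITC/TRITC ratio for a true pH."""
        return (np.asarray(ph, dtype=float) - self.ph_intercept) / self.ph_slope

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise_sd == 0

    def replace(self, **kw) -> "OpticsConfig":
        new = dataclasses.replace(self, **kw)
        new.validate()
        return new


# ---------------------------------------------------------------------------
# Cohort ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """One rod-shaped cell in a trench: offset from the closed end, size."""

    slot: int           # stacking order, 0 = mother at the closed end
    pos_um: float       # top of the cell, distance from the closed end
    length_um: float
    width_um: float

    @property
    def centroid_um(self) -> float:
        return self.pos_um + self.length_um / 2.0


@dataclass(frozen=True)
class LineageTruth:
    lineage_id: int
    trench_id: int
    fate: str                      # one of presets.SUBFATES
    true_ph: np.ndarray            # per scheduled frame; NaN after lysis
    expression: float              # base fluorophore level, arbitrary units
    expression_factor: np.ndarray  # per-frame multiplier on expression
    division_times: tuple[float, ...]
    lysis_time: float | None
    pi_fold: float
    pi_positive: bool
    cells_per_frame: tuple[tuple[CellGeometry, ...], ...]

    def alive_at(self, frame_idx: int) -> bool:
        return len(self.cells_per_frame[frame_idx]) > 0


@dataclass(frozen=True)
class CohortGroundTruth:
    preset_name: str
    schedule_h: tuple[float, ...]
    lineages: tuple[LineageTruth, ...]

    def __len__(self) -> int:
        return len(self.lineages)

    def fate_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lin in self.lineages:
            out[lin.fate] = out.get(lin.fate, 0) + 1
        return out

    def to_frame(self, optics: OpticsConfig | None = None) -> pd.DataFrame:
        """Long-format truth table, one row per lineage per scheduled frame.

        ``fitc``/``tritc`` are the mother cell's noiseless-equivalent
        intensities (background-free expected counts) under ``optics``
        (defaults used when omitted).
        """
        optics = optics or OpticsConfig()
        rows = []
        for lin in self.lineages:
            for k, t in enumerate(self.schedule_h):
                alive = lin.alive_at(k)
                ph = lin.true_ph[k]
                tritc = (lin.expression * lin.expression_factor[k]
                         * optics.tritc_counts) if alive else np.nan
                fitc = optics.ratio_for_ph(ph) * tritc if alive else np.nan
                rows.append((lin.lineage_id, lin.trench_id, t, lin.fate,
                             ph if alive else np.nan, lin.expression,
                             fitc, tritc))
        return pd.DataFrame(rows, columns=[
            "lineage_id", "trench_id", "frame_h", "fate", "true_ph",
            "expression", "fitc", "tritc"])


def _geometry(fate: str, t: float, L0: float, width: float,
              division_times: tuple[float, ...],
              lysis_time: float | None,
              gap_um: float = 0.5, top_um: float = 0.8,
              ) -> tuple[CellGeometry, ...]:
    """Cells present in the trench at time ``t`` for one lineage.

    Non-growing fates keep a single mother of constant size.  Persister
    mothers elongate toward 2x their birth length before each division and
    split into two cells that tile the elongated footprint, so that frame-
    to-frame pixel overlap links mother and daughters unambiguously.
    """
    if lysis_time is not None and t >= lysis_time:
        return ()
    lengths: list[float]
    if fate != "persister" or t <= 3.0 or not division_times:
        lengths = [L0]
    else:
        d1 = division_times[0]
        d2 = division_times[1] if len(division_times) > 1 else None
        if t < d1:
            frac = (t - 3.0) / (d1 - 3.0)
            lengths = [L0 * (1.0 + frac)]
        elif d2 is None or t < d2:
            frac = 0.0 if d2 is None else (t - d1) / (d2 - d1)
            lengths = [L0, L0 * (1.0 + frac)]
        else:
            lengths = [L0, L0, L0]
    cells = []
    y = top_um
    for slot, length in enumerate(lengths):
        cells.append(CellGeometry(slot, y, length, width))
        y += length + gap_um
    return tuple(cells)


def make_cohort(preset: StrainPreset, n_lineages: int, seed: int,
                ) -> CohortGroundTruth:
    """Draw a ground-truthed cohort of mother-cell lineages.

    Fates are i.i.d. from ``preset.fate_probs`` (susceptible lineages are
    further split into lysed / not-lysed); the t = 0 pH comes from the
    fate's mixture and later frames follow the linearly interpolated
    anchor trajectory plus i.i.d. Gaussian noise.  Deterministic given
    ``seed``.
    """
    preset.validate()
    if n_lineages < 1:
        raise PresetError("n_lineages: must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.asarray(IMAGING_SCHEDULE_H)
    nT = len(times)

    fate_idx = rng.choice(3, size=n_lineages, p=np.asarray(preset.fate_probs))
    lysed_draw = rng.random(n_lineages) < preset.susceptible_lysed_fraction
    # log-normal expression: arithmetic mean m, CV c
    sigma2 = np.log1p(preset.expression_cv ** 2)
    mu = np.log(preset.expression_mean) - sigma2 / 2.0
    expression = rng.lognormal(mu, np.sqrt(sigma2), size=n_lineages)
    L0 = rng.uniform(2.5, 3.5, size=n_lineages)
    width = rng.uniform(1.0, 1.2, size=n_lineages)

    lineages = []
    for i in range(n_lineages):
        base_fate = FATES[fate_idx[i]]
        if base_fate == "susceptible":
            fate = "susceptible_lysed" if lysed_draw[i] else "susceptible_not_lysed"
        else:
            fate = base_fate

        t0_ph = preset.t0_ph_dist[base_fate].sample(1, rng)[0]
        anchors = preset.anchor_ph(base_fate, times)
        noise = rng.normal(0.0, preset.trajectory_noise_sd, size=nT)
        ph = anchors + noise
        ph[0] = t0_ph
        ph = np.clip(ph, *PH_HARD_RANGE)

        division_times: tuple[float, ...] = ()
        lysis_time = None
        if fate == "persister":
            d0, d1 = preset.division_window_h
            first = rng.uniform(d0, d1)
            second = first + rng.uniform(3.0, 10.0)
            division_times = (first, second) if second <= 23.0 else (first,)
        elif fate == "susceptible_lysed":
            lysis_time = rng.uniform(*preset.lysis_window_h)
            ph[times >= lysis_time] = np.nan

        factor24 = preset.expression_24h_factor[fate]
        expr_factor = 1.0 + (factor24 - 1.0) * np.clip(
            (times - 3.0) / 21.0, 0.0, 1.0)

        cells = tuple(
            _geometry(fate, t, L0[i], width[i], division_times, lysis_time)
            for t in times)
        pi_fold = preset.pi_fold_change[fate]
        lineages.append(LineageTruth(
            lineage_id=i, trench_id=i, fate=fate, true_ph=ph,
            expression=float(expression[i]), expression_factor=expr_factor,
            division_times=division_times, lysis_time=lysis_time,
            pi_fold=pi_fold, pi_positive=bool(pi_fold >= 2.0),
            cells_per_frame=cells))

    return CohortGroundTruth(preset.name, tuple(float(t) for t in times),
                             tuple(lineages))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """One field of view: a 2-channel time-lapse raster over some trenches.

    ``fitc``/``tritc`` have shape ``(T, H, W)``; ``tritc_post_pi`` is the
    extra TRITC frame acquired after propidium-iodide staining (or None).
    Noiseless renders are float64 expected counts; noisy renders are
    quantized to the configured bit depth.
    """

    times_h: tuple[float, ...]
    fitc: np.ndarray
    tritc: np.ndarray
    trench_ids: tuple[int, ...]
    optics: OpticsConfig
    tritc_post_pi: np.ndarray | None = None

    def trench_rects(self) -> list[tuple[int, int, int, int]]:
        """Ground-truth trench rectangles (r0, r1, c0, c1), half-open."""
        o = self.optics
        ppm = o.pixels_per_micron
        r0 = int(round(o.margin_um * ppm))
        r1 = int(round((o.margin_um + o.trench_length_um) * ppm))
        rects = []
        for k in range(len(self.trench_ids)):
            cc = (k + 0.5) * o.trench_pitch_um * ppm
            half = o.trench_width_um * ppm / 2.0
            rects.append((r0, r1, int(round(cc - half)), int(round(cc + half))))
        return rects

    def write_tiff(self, outdir: str | Path, stem: str = "stack") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / f"{stem}_fitc.tif", self.fitc)
        tifffile.imwrite(outdir / f"{stem}_tritc.tif", self.tritc)
        if self.tritc_post_pi is not None:
            tifffile.imwrite(outdir / f"{stem}_tritc_post_pi.tif",
                             self.tritc_post_pi)
        meta = {
            "times_h": [float(t) for t in self.times_h],
            "trench_ids": [int(t) for t in self.trench_ids],
            "optics": dataclasses.asdict(self.optics),
        }
        (outdir / f"{stem}_meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def read_tiff(cls, outdir: str | Path, stem: str = "stack") -> "FrameStack":
        outdir = Path(outdir)
        meta = yaml.safe_load((outdir / f"{stem}_meta.yaml").read_text())
        post = outdir / f"{stem}_tritc_post_pi.tif"
        return cls(
            times_h=tuple(meta["times_h"]),
            fitc=tifffile.imread(outdir / f"{stem}_fitc.tif"),
            tritc=tifffile.imread(outdir / f"{stem}_tritc.tif"),
            trench_ids=tuple(meta["trench_ids"]),
            optics=OpticsConfig(**meta["optics"]),
            tritc_post_pi=tifffile.imread(post) if post.exists() else None,
        )


def _capsule_mask(h: int, w: int, r_top: float, r_bot: float, c_center: float,
                  radius: float) -> np.ndarray:
    """Boolean rod (rectangle with semicircular caps) on an (h, w) grid."""
    rr, cc = np.mgrid[0:h, 0:w]
    seg_top = r_top + radius
    seg_bot = r_bot - radius
    r_clamped = np.clip(rr, seg_top, max(seg_top, seg_bot))
    return (rr - r_clamped) ** 2 + (cc - c_center) ** 2 <= radius ** 2


def _fov_shape(optics: OpticsConfig, n_trenches: int) -> tuple[int, int]:
    ppm = optics.pixels_per_micron
    h = int(round((optics.trench_length_um + 2 * optics.margin_um) * ppm))
    w = int(round(n_trenches * optics.trench_pitch_um * ppm))
    return h, w


def _paint_channels(optics: OpticsConfig, n_trenches: int,
                    cells: list[tuple[int, CellGeometry, float, float]],
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Expected (noise-free, pre-PSF) FITC and TRITC count images.

    ``cells``: (local trench index, geometry, fitc_density, tritc_density).
    """
    h, w = _fov_shape(optics, n_trenches)
    ppm = optics.pixels_per_micron
    fitc = np.full((h, w), float(optics.background_outside))
    tritc = np.full((h, w), float(optics.background_outside))
    r0 = int(round(optics.margin_um * ppm))
    r1 = int(round((optics.margin_um + optics.trench_length_um) * ppm))
    for k in range(n_trenches):
        cc = (k + 0.5) * optics.trench_pitch_um * ppm
        half = optics.trench_width_um * ppm / 2.0
        c0, c1 = int(round(cc - half)), int(round(cc + half))
        fitc[r0:r1, c0:c1] = optics.background_in_trench
        tritc[r0:r1, c0:c1] = optics.background_in_trench
    for k, geom, f_dens, t_dens in cells:
        cc = (k + 0.5) * optics.trench_pitch_um * ppm
        top = optics.margin_um * ppm + geom.pos_um * ppm
        bot = top + geom.length_um * ppm
        radius = geom.width_um * ppm / 2.0
        if bot > r1:
            raise GenerationError(
                f"trench capacity exceeded: cell extends to {bot/ppm:.2f} um "
                f"in a {optics.trench_length_um} um trench")
        rb0 = max(int(top - radius) - 1, 0)
        rb1 = min(int(bot + radius) + 2, h)
        cb0 = max(int(cc - radius) - 1, 0)
        cb1 = min(int(cc + radius) + 2, w)
        mask = _capsule_mask(rb1 - rb0, cb1 - cb0, top - rb0, bot - rb0,
                             cc - cb0, radius)
        fitc[rb0:rb1, cb0:cb1][mask] += f_dens
        tritc[rb0:rb1, cb0:cb1][mask] += t_dens
    return fitc, tritc


def _detect(optics: OpticsConfig, expected: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Apply PSF blur and the detector noise model; quantize if noisy."""
    img = ndimage.gaussian_filter(
        expected, optics.psf_sigma_um * optics.pixels_per_micron)
    if optics.noiseless:
        return img
    if optics.shot_noise:
        img = rng.poisson(img).astype(float)
    if optics.read_noise_sd > 0:
        img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
    maxval = 2 ** optics.bit_depth - 1
    return np.clip(np.round(img), 0, maxval).astype(np.uint16)


def _cell_densities(optics: OpticsConfig, lin: LineageTruth, frame_idx: int,
                    ) -> tuple[float, float]:
    ph = lin.true_ph[frame_idx]
    tritc = lin.expression * lin.expression_factor[frame_idx] * optics.tritc_counts
    fitc = float(optics.ratio_for_ph(ph)) * tritc
    return fitc, tritc


def render_stack(cohort: CohortGroundTruth, optics: OpticsConfig | None = None,
                 mode: str = "image", seed: int = 0,
                 ) -> list[FrameStack] | pd.DataFrame:
    """Render a cohort as image stacks (one per field of view) or traces.

    In ``image`` mode each group of ``optics.trenches_per_fov`` lineages
    becomes one :class:`FrameStack`.  In ``trace`` mode the per-cell
    noiseless-equivalent intensities (background-free expected counts) are
    emitted directly as a table with columns ``trench_id, frame_h, phase,
    cell_slot, pos_um, length_um, width_um, fitc, tritc``.
    """
    optics = optics or OpticsConfig()
    optics.validate()
    if mode == "trace":
        rows = []
        for lin in cohort.lineages:
            for k, t in enumerate(cohort.schedule_h):
                if not lin.alive_at(k):
                    continue
                f_dens, t_dens = _cell_densities(optics, lin, k)
                for geom in lin.cells_per_frame[k]:
                    rows.append((lin.trench_id, t, "timelapse", geom.slot,
                                 geom.pos_um, geom.length_um, geom.width_um,
                                 f_dens, t_dens))
        return pd.DataFrame(rows, columns=[
            "trench_id", "frame_h", "phase", "cell_slot", "pos_um",
            "length_um", "width_um", "fitc", "tritc"])
    if mode != "image":
        raise ValueError(f"mode must be 'image' or 'trace', got {mode!r}")

    rng = np.random.default_rng(seed)
    per_fov = optics.trenches_per_fov
    stacks = []
    for start in range(0, len(cohort.lineages), per_fov):
        fov = cohort.lineages[start:start + per_fov]
        n_tr = len(fov)
        fitc_frames, tritc_frames = [], []
        for k in range(len(cohort.schedule_h)):
            cells = []
            for local, lin in enumerate(fov):
                if not lin.alive_at(k):
                    continue
                f_dens, t_dens = _cell_densities(optics, lin, k)
                for geom in lin.cells_per_frame[k]:
                    cells.append((local, geom, f_dens, t_dens))
            fitc_exp, tritc_exp = _paint_channels(optics, n_tr, cells)
            fitc_frames.append(_detect(optics, fitc_exp, rng))
            tritc_frames.append(_detect(optics, tritc_exp, rng))
        stacks.append(FrameStack(
            times_h=cohort.schedule_h,
            fitc=np.stack(fitc_frames), tritc=np.stack(tritc_frames),
            trench_ids=tuple(lin.trench_id for lin in fov),
            optics=optics))
    return stacks


def render_calibration_set(standards: list[float],
                           optics: OpticsConfig | None = None,
                           seed: int = 0, n_cells: int = 24,
                           ) -> list[FrameStack]:
    """Render one single-frame stack per pH standard.

    Every cell in a standard's stack has true pH equal to that standard
    (the protonophore-equilibration contract behind the standard curve);
    expression still varies cell to cell, which is exactly what the ratio
    is meant to cancel.
    """
    optics = optics or OpticsConfig()
    optics.validate()
    if not standards:
        raise ValueError("standards: need at least one pH standard")
    lo, hi = PH_HARD_RANGE
    for s in standards:
        if not lo <= s <= hi:
            raise ValueError(f"standard {s} outside ratio-map domain [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(0.25 ** 2)
    stacks = []
    for s_idx, standard in enumerate(standards):
        ratio = float(optics.ratio_for_ph(standard))
        cells = []
        for k in range(n_cells):
            expr = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2))
            length = rng.uniform(2.5, 3.5)
            widthc = rng.uniform(1.0, 1.2)
            geom = CellGeometry(0, 0.8, length, widthc)
            t_dens = expr * optics.tritc_counts
            cells.append((k, geom, ratio * t_dens, t_dens))
        n_tr = n_cells
        fitc_exp, tritc_exp = _paint_channels(optics, n_tr, cells)
        stacks.append(FrameStack(
            times_h=(0.0,),
            fitc=_detect(optics, fitc_exp, rng)[None],
            tritc=_detect(optics, tritc_exp, rng)[None],
            trench_ids=tuple(range(n_tr)),
            optics=optics))
    return stacks


def apply_pi_event(cohort: CohortGroundTruth,
                   stack: FrameStack | pd.DataFrame,
                   seed: int = 0,
                   optics: OpticsConfig | None = None):
    """Append the post-propidium-iodide TRITC acquisition.

    Each cell surviving at 24 h re-emits TRITC multiplied by its fate's
    PI fold change (>1 for membrane-compromised susceptible cells, ~1 for
    viable persister/VBNC cells); lysed cells emit nothing.  Returns the
    stack (mutated) or the extended trace table.
    """
    if isinstance(stack, pd.DataFrame):
        if not (stack["frame_h"] == 24.0).any():
            raise ValueError("trace table has no 24 h frame")
        trace_optics = optics or OpticsConfig()
        k24 = cohort.schedule_h.index(24.0)
        by_id = {lin.trench_id: lin for lin in cohort.lineages}
        rows = []
        for lin in by_id.values():
            if not lin.alive_at(k24):
                continue
            _, t_dens = _cell_densities(trace_optics, lin, k24)
            for geom in lin.cells_per_frame[k24]:
                rows.append((lin.trench_id, 24.0, "post_pi", geom.slot,
                             geom.pos_um, geom.length_um, geom.width_um,
                             np.nan, t_dens * lin.pi_fold))
        post = pd.DataFrame(rows, columns=list(stack.columns))
        return pd.concat([stack, post], ignore_index=True)

    if 24.0 not in stack.times_h:
        raise ValueError("stack has no 24 h frame; cannot apply PI event")
    k24 = stack.times_h.index(24.0)
    optics = stack.optics
    rng = np.random.default_rng(seed)
    by_id = {lin.trench_id: lin for lin in cohort.lineages}
    cells = []
    for local, tid in enumerate(stack.trench_ids):
        lin = by_id[tid]
        if not lin.alive_at(k24):
            continue
        _, t_dens = _cell_densities(optics, lin, k24)
        for geom in lin.cells_per_frame[k24]:
            cells.append((local, geom, 0.0, t_dens * lin.pi_fold))
    _, tritc_exp = _paint_channels(optics, len(stack.trench_ids), cells)
    stack.tritc_post_pi = _detect(optics, tritc_exp, rng)
    return stack
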
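"""Background-subtracted per-cell intensities and the ratiometric signal.

The background of each trench is the average fluorescence of the in-trench
pixels that contain no bacteria; it is subtracted from the mean intensity
over each cell mask, and the pH-reporting ratio is

    R = I_FITC / I_TRITC

which cancels expression level and plasmid copy number because both
channels scale with them identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import CellMask

__all__ = ["PhotometryRecord", "BackgroundError",
           "estimate_background", "measure_cell"]


class BackgroundError(RuntimeError):
    """No background pixels available anywhere."""


@dataclass(frozen=True)
class PhotometryRecord:
    """One cell in one frame: background-subtracted means and the ratio."""

    lineage_id: int
    frame_h: float
    i_fitc: float
    i_tritc: float
    b_fitc: float
    b_tritc: float
    ratio: float           # NaN when I_TRITC <= 0
    flags: tuple[str, ...] = ()

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.ratio)


def estimate_background(fitc: np.ndarray, tritc: np.ndarray,
                        masks: list[CellMask],
                        dilate_px: int = 2,
                        border_px: int = 3,
                        min_pixels: int = 10,
                        fallback: tuple[float, float] | None = None,
                        statistic: str = "mean",
                        ) -> tuple[float, float]:
    """Per-channel background from in-trench pixels outside all masks.

    Masks are dilated a little before exclusion so that light blurred out
    of the cells does not inflate the estimate, and a border ring of the
    crop is excluded because the optical blur of the trench walls mixes
    in the darker outside-trench level there.  When fewer than
    ``min_pixels`` background pixels remain (trench full of cells) the
    ``fallback`` (e.g. a frame-level background) is returned; with no
    fallback either, a :class:`BackgroundError` is raised.
    """
    occupied = np.zeros(fitc.shape, dtype=bool)
    for m in masks:
        occupied |= m.to_bool()
    if dilate_px > 0 and occupied.any():
        occupied = ndimage.binary_dilation(occupied, iterations=dilate_px)
    if border_px > 0:
        h, w = occupied.shape
        b = min(border_px, (min(h, w) - 1) // 2)
        if b > 0:
            occupied[:b, :] = True
            occupied[-b:, :] = True
            occupied[:, :b] = True
            occupied[:, -b:] = True
    bg = ~occupied
    if bg.sum() < min_pixels:
        if fallback is not None:
            return fallback
        raise BackgroundError("no background pixels available in trench")
    stat = np.mean if statistic == "mean" else np.median
    return float(stat(fitc[bg])), float(stat(tritc[bg]))


def measure_cell(mask: CellMask, fitc: np.ndarray, tritc: np.ndarray,
                 b_fitc: float, b_tritc: float,
                 low_signal_floor: float = 10.0,
                 lineage_id: int = -1) -> PhotometryRecord:
    """Background-subtracted mean intensities and the ratio for one mask.

    A non-positive TRITC signal yields a record with an undefined ratio
    and a QC flag rather than an exception; a TRITC signal below the
    low-signal floor (default 5x a 2-count read noise) is flagged
    ``low_signal`` because the ratio of two small numbers is unstable.
    """
    if mask.area_px == 0:
        raise ValueError("empty mask")
    rows, cols = mask.pixels[:, 0], mask.pixels[:, 1]
    i_fitc = float(fitc[rows, cols].mean()) - b_fitc
    i_tritc = float(tritc[rows, cols].mean()) - b_tritc
    flags: list[str] = []
    if i_tritc <= 0:
        ratio = float("nan")
        flags.append("ratio_undefined")
    else:
        ratio = i_fitc / i_tritc
        if i_tritc < low_signal_floor:
            flags.append("low_signal")
    return PhotometryRecord(
        lineage_id=lineage_id, frame_h=mask.frame_h,
        i_fitc=i_fitc, i_tritc=i_tritc,
        b_fitc=b_fitc, b_tritc=b_tritc,
        ratio=ratio, flags=tuple(flags))
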
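"""The linear ratio -> pH standard curve.

The pH reporter responds linearly to pH between 6.5 and 8.0, so a
protonophore-equilibrated calibration series at known external pH values
defines a line ``pH = a * R + b``.  We regress pH on the per-standard mean
ratio directly (the inverse map is the one the pipeline applies), and the
fitted model flags estimates outside the linear regime as invalid; they
are excluded from downstream means and histograms but kept in the tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .presets import PH_VALID_RANGE

__all__ = ["CalibrationModel", "CalibrationError",
           "fit_calibration", "ratio_to_ph",
           "calibration_points_from_stacks"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted standard curve ``pH = slope * R + intercept`` with
    diagnostics, valid over the reporter's linear regime."""

    slope: float
    intercept: float
    valid_range: tuple[float, float] = PH_VALID_RANGE
    n_points: int = 0
    residual_sd: float = float("nan")
    r_squared: float = float("nan")
    standards: tuple[float, ...] = ()
    mean_ratios: tuple[float, ...] = ()

    def ratio_to_ph(self, ratio):
        """Vectorized inverse map; returns ``(ph, valid)`` arrays.

        Undefined ratios (NaN) propagate to undefined, invalid pH.
        """
        r = np.asarray(ratio, dtype=float)
        ph = self.slope * r + self.intercept
        lo, hi = self.valid_range
        valid = np.isfinite(ph) & (ph >= lo) & (ph <= hi)
        if np.isscalar(ratio):
            return float(ph), bool(valid)
        return ph, valid

    def summary(self) -> str:
        lines = [
            "Ratiometric pH calibration (pH = a*R + b)",
            f"  slope a      : {self.slope:.6g} pH / ratio unit",
            f"  intercept b  : {self.intercept:.6g} pH",
            f"  standards    : {self.n_points}",
            f"  residual SD  : {self.residual_sd:.3g} pH",
            f"  R^2          : {self.r_squared:.6g}",
            f"  valid range  : [{self.valid_range[0]}, {self.valid_range[1]}] pH",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        d = {
            "slope": float(self.slope), "intercept": float(self.intercept),
            "valid_range": list(self.valid_range),
            "n_points": self.n_points,
            "residual_sd": float(self.residual_sd),
            "r_squared": float(self.r_squared),
            "standards": list(self.standards),
            "mean_ratios": list(self.mean_ratios),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        d = yaml.safe_load(Path(path).read_text())
        return cls(slope=d["slope"], intercept=d["intercept"],
                   valid_range=tuple(d["valid_range"]),
                   n_points=d["n_points"], residual_sd=d["residual_sd"],
                   r_squared=d["r_squared"],
                   standards=tuple(d["standards"]),
                   mean_ratios=tuple(d["mean_ratios"]))


def fit_calibration(points: list[tuple[float, np.ndarray]],
                    ) -> CalibrationModel:
    """Ordinary least squares of pH on per-standard mean ratio.

    ``points`` pairs each pH standard with the per-cell ratios measured in
    its calibration stack; ratios are averaged per standard first so every
    standard carries equal weight.  Needs >= 2 distinct standards with
    distinct mean ratios.
    """
    if len(points) < 2:
        raise CalibrationError("need at least 2 calibration standards")
    phs = np.array([float(p) for p, _ in points])
    ratios = np.array([float(np.mean(np.asarray(r, dtype=float)))
                       for _, r in points])
    if len(set(phs.tolist())) < 2:
        raise CalibrationError("calibration standards must be distinct")
    if np.ptp(ratios) == 0:
        raise CalibrationError(
            "degenerate calibration: identical mean ratios at all standards")
    # sort for order-invariance of the accumulated sums
    order = np.argsort(ratios, kind="stable")
    x, y = ratios[order], phs[order]
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    resid = y - fitted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(x)
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationModel(
        slope=float(slope), intercept=float(intercept),
        n_points=n, residual_sd=residual_sd, r_squared=float(r_squared),
        standards=tuple(float(v) for v in phs[order]),
        mean_ratios=tuple(float(v) for v in x))


def ratio_to_ph(model: CalibrationModel, ratio):
    """Functional form of :meth:`CalibrationModel.ratio_to_ph`."""
    return model.ratio_to_ph(ratio)


def calibration_points_from_stacks(stacks, standards,
                                   min_area_um2: float = 0.5,
                                   ) -> list[tuple[float, np.ndarray]]:
    """Measure per-cell ratios in rendered calibration stacks.

    Runs the same trench detection / segmentation / photometry chain used
    for experiments on each standard's stack and collects the defined
    per-cell ratios.
    """
    from .pipeline import photometer_frame  # local import; no cycle at runtime

    if len(stacks) != len(standards):
        raise CalibrationError("one stack per standard required")
    points = []
    for stack, standard in zip(stacks, standards):
        records = photometer_frame(stack, frame_idx=0,
                                   min_area_um2=min_area_um2)
        ratios = np.array([rec.ratio for rec in records if rec.ratio_defined])
        if ratios.size == 0:
            raise CalibrationError(
                f"no measurable cells in calibration stack at pH {standard}")
        points.append((float(standard), ratios))
    return points
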
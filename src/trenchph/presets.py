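"""Per-strain generative presets for the synthetic mother-machine assay.

A :class:`StrainPreset` bundles everything the cohort generator needs to
emulate one experimental condition: the probabilities that a mother cell
turns out to be a persister, a VBNC cell, or susceptible; the distribution
of intracellular pH at t = 0 for each fate; the mean pH trajectory over the
treatment/regrowth timeline; fluorophore-expression variability; the
propidium-iodide response; and, for susceptible cells that lyse, the time
window in which they disappear from the trench.

Four presets ship with the package, one per experimental condition:
``parental``, ``delta_tnaA``, ``delta_tnaA_indole_0.5mM`` (persistent
indole signalling, 0.5 mM in the overnight culture) and
``delta_tnaA_indole_pulse_5mM`` (a 20-min 5 mM indole pulse, which leaves
the pH distributions of the knockout essentially unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MixtureND",
    "StrainPreset",
    "PresetError",
    "load_preset",
    "builtin_preset_names",
]

#: Fate labels used throughout the package.  ``susceptible_lysed`` and
#: ``susceptible_not_lysed`` are sub-fates of the ``susceptible`` class.
FATES = ("persister", "vbnc", "susceptible")
SUBFATES = ("persister", "vbnc", "susceptible_lysed", "susceptible_not_lysed")

#: Imaging schedule in hours: hourly from 0 to 6 h, then a final frame at 24 h.
IMAGING_SCHEDULE_H = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 24.0)

#: Linear range of the pH reporter; estimates outside are flagged invalid.
PH_VALID_RANGE = (6.5, 8.0)

#: Hard physical range the generator allows for true pH values.
PH_HARD_RANGE = (6.0, 8.5)


class PresetError(ValueError):
    """Raised when a preset violates one of its invariants."""


@dataclass(frozen=True)
class MixtureND:
    """Mixture of at most two normal components (in pH units)."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def validate(self, name: str = "mixture") -> None:
        k = len(self.means)
        if not (1 <= k <= 2):
            raise PresetError(f"{name}: needs 1 or 2 components, got {k}")
        if len(self.sds) != k or len(self.weights) != k:
            raise PresetError(f"{name}: means/sds/weights lengths differ")
        if any(s <= 0 for s in self.sds):
            raise PresetError(f"{name}: component SDs must be positive")
        if any(w < 0 for w in self.weights):
            raise PresetError(f"{name}: negative mixture weight")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise PresetError(f"{name}: weights must sum to 1")
        lo, hi = PH_HARD_RANGE
        if any(not (lo <= m <= hi) for m in self.means):
            raise PresetError(f"{name}: component mean outside [{lo}, {hi}]")

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values, rejection-truncated to the hard pH range."""
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        x = rng.normal(np.take(self.means, comp), np.take(self.sds, comp))
        lo, hi = PH_HARD_RANGE
        bad = (x < lo) | (x > hi)
        while bad.any():
            comp = rng.choice(len(self.weights), size=int(bad.sum()),
                              p=np.asarray(self.weights))
            x[bad] = rng.normal(np.take(self.means, comp), np.take(self.sds, comp))
            bad = (x < lo) | (x > hi)
        return x


@dataclass(frozen=True)
class StrainPreset:
    """Generative parameters for one strain/condition.

    Parameters
    ----------
    name
        Identifier, e.g. ``"parental"``.
    fate_probs
        ``(P(persister), P(vbnc), P(susceptible))``; must sum to 1.
    susceptible_lysed_fraction
        Among susceptible lineages, the fraction that lyse and disappear.
    t0_ph_dist
        Per-fate mixture (<=2 normal components) of intracellular pH at t=0.
    trajectory_anchors
        Per-fate list of ``(time_h, mean_pH)`` pairs over the imaging
        schedule; mean pH at intermediate times is linearly interpolated.
    trajectory_noise_sd
        SD (pH units) of the frame-to-frame noise around the anchor curve.
    expression_mean, expression_cv
        Log-normal fluorophore production level (copy-number proxy):
        arithmetic mean and coefficient of variation.
    expression_24h_factor
        Per-sub-fate multiplicative change of expression by 24 h (viable
        cells keep expressing, dead non-lysed cells degrade their
        fluorophores).  Ramped linearly from 1.0 at drug removal (3 h).
    pi_fold_change
        Per-sub-fate multiplicative TRITC change upon propidium iodide
        (>1 for membrane-compromised cells, ~1 for viable ones).
    lysis_window_h
        ``(t_min, t_max)``: susceptible_lysed cells draw their lysis time
        uniformly in this interval.
    division_window_h
        Persister first-division time is drawn uniformly here (after drug
        removal at 3 h).
    """

    name: str
    fate_probs: tuple[float, float, float]
    t0_ph_dist: dict[str, MixtureND]
    trajectory_anchors: dict[str, tuple[tuple[float, float], ...]]
    trajectory_noise_sd: float = 0.1
    susceptible_lysed_fraction: float = 0.9
    expression_mean: float = 1.0
    expression_cv: float = 0.25
    expression_24h_factor: dict[str, float] = field(default_factory=lambda: {
        "persister": 2.0, "vbnc": 2.0,
        "susceptible_not_lysed": 0.2, "susceptible_lysed": 1.0,
    })
    pi_fold_change: dict[str, float] = field(default_factory=lambda: {
        "persister": 1.0, "vbnc": 1.0,
        "susceptible_not_lysed": 3.0, "susceptible_lysed": 1.0,
    })
    lysis_window_h: tuple[float, float] = (3.5, 10.0)
    division_window_h: tuple[float, float] = (4.0, 8.0)

    def validate(self) -> None:
        p = np.asarray(self.fate_probs, dtype=float)
        if p.shape != (3,):
            raise PresetError("fate_probs: must be a triple")
        if (p < 0).any():
            raise PresetError("fate_probs: probabilities must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise PresetError(
                f"fate_probs: must sum to 1 (got {p.sum():.12g})")
        if not 0.0 <= self.susceptible_lysed_fraction <= 1.0:
            raise PresetError("susceptible_lysed_fraction: must be in [0, 1]")
        for fate in FATES:
            if fate not in self.t0_ph_dist:
                raise PresetError(f"t0_ph_dist: missing fate '{fate}'")
            self.t0_ph_dist[fate].validate(f"t0_ph_dist[{fate}]")
            if fate not in self.trajectory_anchors:
                raise PresetError(f"trajectory_anchors: missing fate '{fate}'")
            anchors = self.trajectory_anchors[fate]
            if len(anchors) < 2:
                raise PresetError(
                    f"trajectory_anchors[{fate}]: need >= 2 anchors")
            times = [t for t, _ in anchors]
            if sorted(times) != list(times) or len(set(times)) != len(times):
                raise PresetError(
                    f"trajectory_anchors[{fate}]: times must strictly increase")
            lo, hi = PH_HARD_RANGE
            if any(not (lo <= v <= hi) for _, v in anchors):
                raise PresetError(
                    f"trajectory_anchors[{fate}]: pH outside [{lo}, {hi}]")
        if self.trajectory_noise_sd < 0:
            raise PresetError("trajectory_noise_sd: must be >= 0")
        if self.expression_cv < 0 or self.expression_mean <= 0:
            raise PresetError("expression_dist: mean > 0 and CV >= 0 required")
        for d, label in ((self.pi_fold_change, "pi_fold_change"),
                         (self.expression_24h_factor, "expression_24h_factor")):
            for sub in SUBFATES:
                if sub not in d:
                    raise PresetError(f"{label}: missing sub-fate '{sub}'")
        t0, t1 = self.lysis_window_h
        if not (0 < t0 < t1):
            raise PresetError("lysis_window_h: need 0 < t_min < t_max")
        d0, d1 = self.division_window_h
        if not (3.0 < d0 < d1 <= 24.0):
            raise PresetError("division_window_h: must lie within (3, 24]")

    def anchor_ph(self, fate: str, times_h: np.ndarray) -> np.ndarray:
        """Mean pH at ``times_h`` by linear interpolation of the anchors."""
        anchors = self.trajectory_anchors[fate]
        tt = np.array([t for t, _ in anchors])
        vv = np.array([v for _, v in anchors])
        return np.interp(np.asarray(times_h, dtype=float), tt, vv)


# ---------------------------------------------------------------------------
# Serialization (flat YAML mapping) and built-in presets
# ---------------------------------------------------------------------------

def preset_to_dict(preset: StrainPreset) -> dict:
    return {
        "name": preset.name,
        "fate_probs": list(preset.fate_probs),
        "susceptible_lysed_fraction": preset.susceptible_lysed_fraction,
        "t0_ph_dist": {
            fate: {"means": list(m.means), "sds": list(m.sds),
                   "weights": list(m.weights)}
            for fate, m in preset.t0_ph_dist.items()
        },
        "trajectory_anchors": {
            fate: [list(pair) for pair in anchors]
            for fate, anchors in preset.trajectory_anchors.items()
        },
        "trajectory_noise_sd": preset.trajectory_noise_sd,
        "expression_mean": preset.expression_mean,
        "expression_cv": preset.expression_cv,
        "expression_24h_factor": dict(preset.expression_24h_factor),
        "pi_fold_change": dict(preset.pi_fold_change),
        "lysis_window_h": list(preset.lysis_window_h),
        "division_window_h": list(preset.division_window_h),
    }


def preset_from_dict(d: dict) -> StrainPreset:
    def _mix(m: dict) -> MixtureND:
        return MixtureND(tuple(m["means"]), tuple(m["sds"]), tuple(m["weights"]))

    preset = StrainPreset(
        name=d["name"],
        fate_probs=tuple(d["fate_probs"]),
        t0_ph_dist={f: _mix(m) for f, m in d["t0_ph_dist"].items()},
        trajectory_anchors={
            f: tuple(tuple(p) for p in a)
            for f, a in d["trajectory_anchors"].items()
        },
        trajectory_noise_sd=d.get("trajectory_noise_sd", 0.1),
        susceptible_lysed_fraction=d.get("susceptible_lysed_fraction", 0.9),
        expression_mean=d.get("expression_mean", 1.0),
        expression_cv=d.get("expression_cv", 0.25),
        expression_24h_factor=d.get("expression_24h_factor",
                                    StrainPreset.__dataclass_fields__[
                                        "expression_24h_factor"].default_factory()),
        pi_fold_change=d.get("pi_fold_change",
                             StrainPreset.__dataclass_fields__[
                                 "pi_fold_change"].default_factory()),
        lysis_window_h=tuple(d.get("lysis_window_h", (3.5, 10.0))),
        division_window_h=tuple(d.get("division_window_h", (4.0, 8.0))),
    )
    preset.validate()
    return preset


def save_preset(preset: StrainPreset, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(preset_to_dict(preset), sort_keys=False))


_BUILTIN_FILES = {
    "parental": "parental.yaml",
    "delta_tnaA": "delta_tnaA.yaml",
    "delta_tnaA_indole_0.5mM": "delta_tnaA_indole_0.5mM.yaml",
    "delta_tnaA_indole_pulse_5mM": "delta_tnaA_indole_pulse_5mM.yaml",
}


def builtin_preset_names() -> list[str]:
    return list(_BUILTIN_FILES)


def load_preset(name_or_path: str | Path) -> StrainPreset:
    """Load a built-in preset by name, or any preset from a YAML file."""
    key = str(name_or_path)
    if key in _BUILTIN_FILES:
        text = (resources.files("trenchph") / "presets"
                / _BUILTIN_FILES[key]).read_text()
    else:
        text = Path(name_or_path).read_text()
    return preset_from_dict(yaml.safe_load(text))
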
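"""End-point phenotype calls for t = 0 lineages.

After 3 h of ampicillin at 25x MIC and 21 h of drug-free growth, each
lineage that was present before treatment is classified at the 24 h end
point:

1. gone from the trench                        -> susceptible_lysed
2. divided after drug removal (t > 3 h)        -> persister
3. PI-positive or low fluorophore expression   -> susceptible_not_lysed
4. otherwise (intact, expressing, non-dividing) -> vbnc

The propidium-iodide (PI) call compares the TRITC intensity of the cell
before and after the stain flows through the device: membrane-compromised
cells let the DNA stain in and brighten in the red channel, viable cells
do not.  "Low expression" is operationalized as a 24 h TRITC signal below
a percentile cutoff of the t = 0 population, standing in for the visibly
dimmer fluorescent-protein signal of dead, non-lysed cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["LineageEvidence", "PhenotypeCall", "pi_response",
           "classify_lineage", "classify_cohort", "LABELS"]

LABELS = ("persister", "vbnc", "susceptible_lysed", "susceptible_not_lysed")


def pi_response(pre_tritc: float, post_tritc: float,
                threshold: float = 2.0,
                low_signal_floor: float = 10.0,
                ) -> tuple[float, bool]:
    """Fold change of TRITC across the PI stain and the positivity call.

    A pre-stain signal at or below the low-signal floor makes the fold
    undefined (NaN); the classifier treats that as low-expression
    evidence rather than a PI call.
    """
    if not np.isfinite(pre_tritc) or pre_tritc <= low_signal_floor:
        return float("nan"), False
    fold = post_tritc / pre_tritc
    return float(fold), bool(fold >= threshold)


@dataclass(frozen=True)
class LineageEvidence:
    """Observable end-point evidence for one t = 0 lineage."""

    lineage_id: int
    present_at_24h: bool
    divided_after_3h: bool
    t0_tritc: float
    tritc_24h: float = float("nan")       # pre-PI, background-subtracted
    post_pi_tritc: float = float("nan")
    pi_frame_available: bool = True


@dataclass(frozen=True)
class PhenotypeCall:
    lineage_id: int
    label: str
    divided_after_3h: bool
    present_at_24h: bool
    pi_fold: float
    expression_percentile: float


def classify_lineage(ev: LineageEvidence,
                     low_expression_cutoff: float,
                     t0_tritc_population: np.ndarray,
                     pi_threshold: float = 2.0,
                     low_signal_floor: float = 10.0) -> PhenotypeCall:
    """Apply the end-point decision rules to one lineage's evidence."""
    fold = float("nan")
    percentile = float("nan")
    if ev.present_at_24h and np.isfinite(ev.tritc_24h):
        percentile = float(
            100.0 * np.mean(t0_tritc_population <= ev.tritc_24h))
    if not ev.present_at_24h:
        label = "susceptible_lysed"
    elif ev.divided_after_3h:
        label = "persister"
    elif not ev.pi_frame_available:
        label = "indeterminate"
    else:
        fold, positive = pi_response(ev.tritc_24h, ev.post_pi_tritc,
                                     pi_threshold, low_signal_floor)
        low_expression = (not math.isfinite(fold)
                          or ev.tritc_24h < low_expression_cutoff)
        label = "susceptible_not_lysed" if (positive or low_expression) else "vbnc"
    return PhenotypeCall(
        lineage_id=ev.lineage_id, label=label,
        divided_after_3h=ev.divided_after_3h,
        present_at_24h=ev.present_at_24h,
        pi_fold=fold, expression_percentile=percentile)


def classify_cohort(evidences: list[LineageEvidence],
                    low_expression_percentile: float = 10.0,
                    pi_threshold: float = 2.0,
                    low_signal_floor: float = 10.0) -> list[PhenotypeCall]:
    """Classify every t = 0 lineage of a cohort.

    The low-expression cutoff is the given percentile of the t = 0
    TRITC population, computed over all lineages (classification order
    therefore cannot affect any call).  Lineages that survive without
    dividing but lack a PI frame come back ``indeterminate`` with a
    logged warning.
    """
    if not evidences:
        return []
    t0 = np.array([ev.t0_tritc for ev in evidences], dtype=float)
    t0 = t0[np.isfinite(t0)]
    cutoff = float(np.percentile(t0, low_expression_percentile)) if t0.size \
        else float("-inf")
    calls = [classify_lineage(ev, cutoff, t0, pi_threshold, low_signal_floor)
             for ev in evidences]
    n_ind = sum(1 for c in calls if c.label == "indeterminate")
    if n_ind:
        log.warning("classify_cohort: %d surviving non-dividers lack a PI "
                    "frame and are labeled indeterminate", n_ind)
    return calls
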
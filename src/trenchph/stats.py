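"""Population-level summaries: phenotype fractions, pH distributions,
mode detection and the Welch test.

These aggregate the per-cell pipeline outputs into the quantities the
assay reports at population scale: the persister / VBNC / susceptible
composition with binomial errors, per-phenotype pH histograms and
mean +/- SEM time courses, kernel-density mode locations for detecting
bimodality, and unpaired t tests with Welch's correction between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats as sstats

log = logging.getLogger(__name__)

__all__ = ["PhenotypeFractions", "PhDistributionSummary",
           "phenotype_fractions", "ph_distribution", "detect_modes",
           "welch_test"]

#: Default histogram grid: 0.1 pH bins spanning the reporter range.
DEFAULT_BINS = np.round(np.arange(6.4, 8.1001, 0.1), 10)


@dataclass(frozen=True)
class PhenotypeFractions:
    """Persister / VBNC / susceptible composition with binomial SEs."""

    f_persister: float
    f_vbnc: float
    f_susceptible: float
    n_total: int
    se_persister: float
    se_vbnc: float
    se_susceptible: float

    def as_dict(self) -> dict[str, float]:
        return {"persister": self.f_persister, "vbnc": self.f_vbnc,
                "susceptible": self.f_susceptible}


def phenotype_fractions(labels) -> PhenotypeFractions:
    """Fractions of persister, VBNC and susceptible (lysed + non-lysed)
    calls, with per-fraction binomial standard errors.

    Accepts phenotype labels or :class:`~trenchph.phenotyping.PhenotypeCall`
    objects; ``indeterminate`` calls are excluded from the denominator.
    """
    names = [getattr(x, "label", x) for x in labels]
    names = [x for x in names if x != "indeterminate"]
    if not names:
        raise ValueError("no classified lineages")
    n = len(names)
    counts = {
        "persister": sum(1 for x in names if x == "persister"),
        "vbnc": sum(1 for x in names if x == "vbnc"),
        "susceptible": sum(1 for x in names
                           if x in ("susceptible_lysed",
                                    "susceptible_not_lysed", "susceptible")),
    }
    if sum(counts.values()) != n:
        unknown = set(names) - {"persister", "vbnc", "susceptible_lysed",
                                "susceptible_not_lysed", "susceptible"}
        raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")
    f = {k: v / n for k, v in counts.items()}
    se = {k: float(np.sqrt(p * (1 - p) / n)) for k, p in f.items()}
    return PhenotypeFractions(
        f_persister=f["persister"], f_vbnc=f["vbnc"],
        f_susceptible=f["susceptible"], n_total=n,
        se_persister=se["persister"], se_vbnc=se["vbnc"],
        se_susceptible=se["susceptible"])


@dataclass(frozen=True)
class PhDistributionSummary:
    phenotype: str
    time_h: float
    mean: float
    sem: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray
    modes: tuple[float, ...]
    n_excluded: int = 0          # out-of-range / undefined pH values
    flags: tuple[str, ...] = ()


def ph_distribution(values, phenotype: str = "", time_h: float = float("nan"),
                    bins: np.ndarray | None = None,
                    detect_modes_min_n: int = 20) -> PhDistributionSummary:
    """Histogram, mean and SEM of a sample of valid pH values.

    NaN (undefined/out-of-range-flagged) entries are excluded and counted;
    a single value yields SEM 0 by convention with an ``n=1`` flag; an
    empty sample yields an empty summary with a logged warning.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    n_excluded = values.size - finite.size
    edges = DEFAULT_BINS if bins is None else np.asarray(bins, dtype=float)
    flags: list[str] = []
    if finite.size == 0:
        log.warning("ph_distribution: no valid pH values "
                    "(phenotype=%s, t=%s h)", phenotype, time_h)
        return PhDistributionSummary(
            phenotype, time_h, float("nan"), float("nan"), 0, edges,
            np.zeros(len(edges) - 1, dtype=int), (), n_excluded, ("empty",))
    counts, _ = np.histogram(finite, bins=edges)
    mean = float(finite.mean())
    if finite.size == 1:
        sem = 0.0
        flags.append("n=1")
    else:
        sem = float(finite.std(ddof=1) / np.sqrt(finite.size))
    modes: tuple[float, ...] = ()
    if finite.size >= detect_modes_min_n:
        modes = tuple(detect_modes(finite))
    return PhDistributionSummary(
        phenotype, time_h, mean, sem, int(finite.size), edges, counts,
        modes, n_excluded, tuple(flags))


def detect_modes(values, grid_step: float = 0.005,
                 prominence_frac: float = 0.1,
                 min_n: int = 20) -> list[float]:
    """Mode locations of a pH sample by Gaussian kernel density.

    Silverman's-rule bandwidth; local maxima whose prominence exceeds
    ``prominence_frac`` of the peak density are returned in ascending pH
    order.  Requires at least ``min_n`` values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_n:
        raise ValueError(f"detect_modes: need n >= {min_n}, got {values.size}")
    if np.ptp(values) == 0:
        return [float(values[0])]
    kde = sstats.gaussian_kde(values, bw_method="silverman")
    pad = 3.0 * values.std()
    grid = np.arange(values.min() - pad, values.max() + pad + grid_step,
                     grid_step)
    density = kde(grid)
    peaks, _ = signal.find_peaks(density,
                                 prominence=prominence_frac * density.max())
    return sorted(float(grid[p]) for p in peaks)


def welch_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Unpaired t test with Welch's correction.

    Returns ``(t, df, p)`` with the Welch statistic, the Welch-
    Satterthwaite degrees of freedom, and the two-sided p-value from the
    t distribution.  Requires n >= 2 per sample and nonzero variance in
    at least one sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test: each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("welch_test: both samples have zero variance")
    na, nb = a.size, b.size
    ra, rb = va / na, vb / nb
    se2 = ra + rb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # normalized Welch-Satterthwaite form, immune to variance underflow
    fa, fb = ra / se2, rb / se2
    df = 1.0 / (fa ** 2 / (na - 1) + fb ** 2 / (nb - 1))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
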
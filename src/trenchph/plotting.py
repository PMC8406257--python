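"""Quick-look figures for pipeline outputs (matplotlib)."""

from __future__ import annotations

import numpy as np

from .pipeline import AnalysisResult, summarize_ph
from .stats import DEFAULT_BINS

__all__ = ["plot_ph_distribution", "plot_ph_trajectories"]


def plot_ph_distribution(values, ax=None, label: str = "", bins=None):
    """Histogram of single-cell pH values on the standard 0.1-pH grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = DEFAULT_BINS if bins is None else bins
    values = np.asarray(values, dtype=float)
    ax.hist(values[np.isfinite(values)], bins=edges, alpha=0.7, label=label)
    ax.set_xlabel("intracellular pH")
    ax.set_ylabel("cells")
    if label:
        ax.legend()
    return ax


def plot_ph_trajectories(result: AnalysisResult, ax=None):
    """Mean +/- SEM pH over time, one line per phenotype class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    summary = summarize_ph(result)
    for label, g in summary.groupby("label"):
        g = g.sort_values("frame_h")
        ax.errorbar(g["frame_h"], g["mean_ph"], yerr=g["sem"],
                    marker="o", capsize=2, label=label)
    ax.axvspan(0, 3, alpha=0.1, color="grey")  # ampicillin window
    ax.set_xlabel("time (h)")
    ax.set_ylabel("intracellular pH")
    ax.legend()
    return ax
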
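"""Basic plotting helpers: population traces and S/T histograms."""

from __future__ import annotations

import numpy as np

from .normalize import PopulationSummary
from .stats import ST_BINS


def plot_rtot(summary: PopulationSummary, ax=None, label: str | None = None, color=None):
    """Plot R_tot +- SEM against time; stimulus events as vertical lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = summary.timebase.times
    ax.plot(t, summary.r_tot, label=label or summary.experiment_id, color=color)
    ax.fill_between(
        t, summary.r_tot - summary.sem, summary.r_tot + summary.sem, alpha=0.25, color=color
    )
    for lab, ts in summary.timebase.events:
        ax.axvline(ts, ls="--", lw=0.8, color="grey")
        ax.annotate(lab, (ts, ax.get_ylim()[1]), fontsize=8, rotation=90, va="top")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("R_tot (dF, %)")
    return ax


def plot_st_histogram(st_ratios, ax=None, label: str | None = None, color=None):
    """Histogram of S/T ratios on the standard 0.05-wide bins over [0, 1.2]."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    r = np.asarray(st_ratios, dtype=float)
    r = r[~np.isnan(r)]
    ax.hist(np.clip(r, 0, 1.2), bins=ST_BINS, histtype="step", label=label, color=color)
    ax.set_xlabel("S/T ratio")
    ax.set_ylabel("cells")
    return ax
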
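"""Per-arm aggregation and the study's comparative statistics.

The unit of replication is the experiment, not the cell: arm summaries are
computed per experiment first and then averaged (+- SEM) across the
experiments of the arm.  Comparisons between arms use paired two-sided
t-tests (paired by experiment set), a paired t-test on arcsine-transformed
responder proportions, and Pearson's chi-square on 2x2 prolonged-response
contingency tables.  No multiple-testing correction is applied; p-values
are reported raw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

from .metrics import compute_cell_metrics
from .normalize import NormalizedTraceSet, compute_rtot

__all__ = [
    "ContingencyTable2x2",
    "ArmSummary",
    "paired_ttest",
    "arcsine_transform",
    "chi_square_2x2",
    "st_distribution",
    "summarize_arm",
]

#: S/T histogram: fixed 0.05-wide bins over [0, 1.2]
ST_BINS = np.round(np.arange(0.0, 1.2 + 0.05 / 2, 0.05), 10)

#: "early sustained" R_tot window, seconds after progesterone (2.5-3.3 min)
EARLY_SUSTAINED_WINDOW_S = (150.0, 198.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 comparison (rows = arms, columns = outcome/not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError(f"counts must be nonnegative, got {counts}")
        if sum(counts) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def paired_ttest(x, y, labels=None) -> tuple[float, float, int]:
    """Two-sided paired t-test; returns ``(t, p, df)``.

    ``x`` and ``y`` are per-set values paired by position (or by the
    optional ``labels``).  A zero-variance nonzero difference yields p=0
    with a warning; identical vectors yield t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"unpaired inputs: {x.shape} vs {y.shape}")
    if labels is not None:
        if len(labels) != len(x):
            raise ValueError("labels length mismatch")
        missing = [l for l, a, b in zip(labels, x, y) if np.isnan(a) or np.isnan(b)]
        if missing:
            raise ValueError(f"missing paired values for set(s): {missing}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in paired samples")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires >= 2 pairs")
    d = x - y
    df = n - 1
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0, df
        warnings.warn(
            "zero-variance nonzero paired difference: p reported as 0",
            stacklevel=2,
        )
        return math.copysign(float("inf"), d[0]), 0.0, df
    res = ss.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), df


def arcsine_transform(p) -> float | np.ndarray:
    """Variance-stabilizing transform for proportions: arcsin(sqrt(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on a 2x2 table; Yates correction
    optional (default off).  Rejects tables with a zero expected count."""
    arr = table.as_array()
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count in contingency table")
    chi2, p, _, _ = ss.chi2_contingency(arr, correction=yates)
    return float(chi2), float(p)


def st_distribution(st_ratios) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of S/T ratios (0.05-wide bins over [0, 1.2]) and the
    fraction of ratios strictly above 0.9.

    Returns ``(counts, bin_edges, fraction_gt_0_9)``.  NaNs (undefined
    ratios) are ignored; at least one defined ratio is required.
    """
    r = np.asarray(st_ratios, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no defined S/T ratios")
    counts, edges = np.histogram(np.clip(r, 0.0, 1.2), bins=ST_BINS)
    return counts, edges, float(np.mean(r > 0.9))


@dataclass
class ArmSummary:
    """Cross-experiment summary of one treatment arm.

    ``per_experiment`` holds one row per experiment (peak R_tot amplitude,
    early-sustained R_tot amplitude, decay rate, responder proportion,
    prolonged fraction, mean S/T); ``mean`` and ``sem`` aggregate those
    columns across experiments.
    """

    arm: str
    per_experiment: pd.DataFrame
    mean: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)
    st_hist_counts: np.ndarray | None = None
    st_hist_edges: np.ndarray | None = None
    fraction_st_gt_0_9: float = float("nan")
    n_cells: int = 0


def summarize_arm(
    normalized_sets: list[NormalizedTraceSet],
    metrics_tables: list[pd.DataFrame] | None = None,
    early_window_s: tuple[float, float] = EARLY_SUSTAINED_WINDOW_S,
) -> ArmSummary:
    """Aggregate one arm's experiments into an :class:`ArmSummary`.

    Experiment-level values are computed first; the cross-experiment mean
    and SEM follow (the experiment is the unit of replication).  A
    single-experiment arm reports SEM 0 with a warning.
    """
    if not normalized_sets:
        raise ValueError("empty arm: no experiments to summarize")
    if metrics_tables is None:
        metrics_tables = [compute_cell_metrics(n) for n in normalized_sets]
    if len(metrics_tables) != len(normalized_sets):
        raise ValueError("one metrics table per experiment is required")

    arm = normalized_sets[0].design.arm if normalized_sets[0].design else ""
    rows = []
    all_st: list[np.ndarray] = []
    n_cells = 0
    for norm, met in zip(normalized_sets, metrics_tables):
        tb = norm.timebase
        summary = compute_rtot(norm)
        row = {
            "experiment_id": summary.experiment_id,
            "set_id": summary.set_id,
            "n_cells": norm.n_cells,
        }
        if tb.has_event("progesterone"):
            t0 = tb.event_time("progesterone")
            from .metrics import decay_rate, peak_amplitude  # local to avoid cycle

            row["rtot_peak_pct"], _ = peak_amplitude(summary.r_tot, tb, t0)
            win = tb.window(t0 + early_window_s[0], t0 + early_window_s[1])
            row["rtot_early_sustained_pct"] = float(summary.r_tot[win].mean())
            row["rtot_decay_rate_pct_per_min"] = decay_rate(summary.r_tot, tb, t0)
            row["responder_proportion"] = float(met["responder"].mean())
            row["prolonged_fraction"] = float(met["prolonged"].mean())
            st = met["st_ratio"].to_numpy(float)
            row["mean_st_ratio"] = float(np.nanmean(st)) if np.any(~np.isnan(st)) else np.nan
            all_st.append(st[~np.isnan(st)])
        n_cells += norm.n_cells
        rows.append(row)
    per_exp = pd.DataFrame(rows)

    numeric = [c for c in per_exp.columns if c not in ("experiment_id", "set_id")]
    mean = {c: float(np.nanmean(per_exp[c])) for c in numeric}
    if len(per_exp) == 1:
        warnings.warn("single-experiment arm: SEM set to 0", stacklevel=2)
        sem = {c: 0.0 for c in numeric}
    else:
        sem = {
            c: float(np.nanstd(per_exp[c], ddof=1) / np.sqrt(per_exp[c].notna().sum()))
            for c in numeric
        }

    out = ArmSummary(arm=arm, per_experiment=per_exp, mean=mean, sem=sem, n_cells=n_cells)
    if all_st and np.concatenate(all_st).size:
        counts, edges, frac = st_distribution(np.concatenate(all_st))
        out.st_hist_counts = counts
        out.st_hist_edges = edges
        out.fraction_st_gt_0_9 = frac
    return out
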
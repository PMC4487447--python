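"""Per-cell response metrics and detectors for calcium fluorescence traces.

All quantities operate on normalized dF (%) traces and are defined by frame
windows relative to a stimulus time:

* **peak amplitude** — mean of the three frames spanning the post-stimulus
  maximum (search window: stimulus to +120 s);
* **3-min amplitude** — mean of six consecutive frames spanning 2.5-3.5 min
  after the stimulus ([+150 s, +200 s] at 0.1 Hz);
* **decay rate** — least-squares slope of dF over 1.5-2 min post-stimulus,
  in % per minute;
* **S/T ratio** — mean dF over 3-5 min post-stimulus divided by the peak
  amplitude of the preceding transient (sustained / transient);
* **CI-sum responder criterion** — the response is significant when the
  difference between the pre-stimulus mean (10 frames) and the peak mean
  (3 frames) exceeds the sum of the two samples' 95% confidence intervals;
* **prolonged response** — a responder whose 3-min amplitude is at least
  0.9 of its peak amplitude (quantitative proxy for "no discernible decay
  for >= 3 min");
* **oscillation / pause detection** and **dual-ROI synchrony**.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .normalize import NormalizedTraceSet, compute_rtot
from .timebase import TimeBase

__all__ = [
    "DetectionVerdict",
    "peak_amplitude",
    "amplitude_at_3min",
    "decay_rate",
    "st_ratio",
    "detect_responder",
    "classify_prolonged",
    "detect_oscillations",
    "oscillation_events_for_pause",
    "detect_pause",
    "roi_synchrony",
    "compute_cell_metrics",
]

#: default post-stimulus search windows, seconds
PEAK_SEARCH_S = 120.0      # progesterone transient peaks within ~30 s
DIP_SEARCH_S = 180.0       # peptide dip is maximal near ~90 s
PROLONGED_THRESHOLD = 0.9  # 3-min amplitude >= 0.9 x peak


def _window_or_raise(timebase: TimeBase, t0: float, t1: float, what: str) -> np.ndarray:
    if t0 < -1e-9 or t1 > timebase.duration_s + 1e-9:
        raise ValueError(
            f"{what} window [{t0}, {t1}] s extends outside the recording "
            f"[0, {timebase.duration_s}] s"
        )
    return timebase.window(t0, t1)


def _three_point_mean(trace: np.ndarray, idx: int, lo: int, hi: int) -> float:
    """Mean of frames {idx-1, idx, idx+1}, truncated to [lo, hi]."""
    sel = np.arange(max(idx - 1, lo), min(idx + 1, hi) + 1)
    return float(trace[sel].mean())


def peak_amplitude(
    trace: np.ndarray,
    timebase: TimeBase,
    stim_time_s: float,
    search_window_s: tuple[float, float] = (0.0, PEAK_SEARCH_S),
    mode: str = "max",
) -> tuple[float, float]:
    """Peak amplitude (mean of the three frames spanning the extremum) and
    its time relative to the stimulus.

    ``mode="min"`` searches for a minimum (peptide dip).  Ties break toward
    the earliest frame; at the window edges the three-point mean is
    truncated.  The amplitude is measured relative to 0, i.e. the
    post-normalization baseline.
    """
    trace = np.asarray(trace, dtype=float)
    win = _window_or_raise(
        timebase, stim_time_s + search_window_s[0], stim_time_s + search_window_s[1],
        "peak search",
    )
    vals = trace[win]
    rel = int(np.argmin(vals)) if mode == "min" else int(np.argmax(vals))
    idx = int(win[rel])
    amp = _three_point_mean(trace, idx, int(win[0]), int(win[-1]))
    return amp, float(timebase.times[idx] - stim_time_s)


def amplitude_at_3min(trace: np.ndarray, timebase: TimeBase, stim_time_s: float) -> float:
    """Mean of the six consecutive frames spanning 2.5-3.5 min post-stimulus.

    The six frames end two frames after the frame nearest ``stim + 180 s``;
    at 0.1 Hz this selects exactly the frames at +150..+200 s.
    """
    trace = np.asarray(trace, dtype=float)
    centre = timebase.frame_of(stim_time_s + 180.0)
    idx = np.arange(centre - 3, centre + 3)
    if idx[0] < 0 or idx[-1] >= timebase.n_frames:
        raise ValueError(
            "recording does not cover the 2.5-3.5 min post-stimulus window"
        )
    return float(trace[idx].mean())


def decay_rate(trace: np.ndarray, timebase: TimeBase, stim_time_s: float) -> float:
    """Least-squares slope of dF over t in [stim+90 s, stim+120 s], %/min.

    Applied to a single-cell trace or to R_tot; covers the steepest part of
    the falling phase of the transient (4 frames at 0.1 Hz).
    """
    trace = np.asarray(trace, dtype=float)
    win = _window_or_raise(timebase, stim_time_s + 90.0, stim_time_s + 120.0, "decay")
    if len(win) < 2:
        raise ValueError("fewer than 2 frames in the 1.5-2 min decay window")
    t_min = timebase.times[win] / 60.0
    slope = np.polyfit(t_min, trace[win], 1)[0]
    return float(slope)


def st_ratio(
    trace: np.ndarray, timebase: TimeBase, stim_time_s: float, peak_amp_pct: float
) -> float:
    """Sustained/transient ratio: mean dF over [stim+180 s, stim+300 s]
    divided by the transient peak amplitude.

    Undefined (NaN) when the peak amplitude is not positive.  Not clamped;
    values slightly above 1 occur for plateau cells and with noise.
    """
    if not peak_amp_pct > 0:
        return float("nan")
    trace = np.asarray(trace, dtype=float)
    win = _window_or_raise(timebase, stim_time_s + 180.0, stim_time_s + 300.0, "S/T")
    return float(trace[win].mean() / peak_amp_pct)


@dataclass(frozen=True)
class DetectionVerdict:
    """Outcome of the CI-sum responder criterion, with its intermediates."""

    pre_mean: float
    pre_ci95: float
    peak_mean: float
    peak_ci95: float
    significant: bool
    peak_time_s: float = float("nan")

    @property
    def difference(self) -> float:
        return self.peak_mean - self.pre_mean


def _ci95(sample: np.ndarray, convention: str) -> float:
    n = len(sample)
    sem = float(np.std(sample, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    if convention == "normal_1.96":
        return 1.96 * sem
    if convention == "t_based":
        return float(stats.t.ppf(0.975, n - 1) * sem)
    raise ValueError(f"unknown CI convention {convention!r}")


def detect_responder(
    trace: np.ndarray,
    timebase: TimeBase,
    stim_time_s: float,
    direction: str = "increase",
    search_window_s: tuple[float, float] | None = None,
    ci_convention: str = "normal_1.96",
    n_pre: int = 10,
) -> DetectionVerdict:
    """Apply the CI-sum criterion: significant iff the difference between
    the pre-stimulus mean (``n_pre`` frames immediately before the
    stimulus) and the peak mean (three frames spanning the post-stimulus
    extremum) exceeds the sum of the two samples' 95% CIs, with the sign of
    the difference matching ``direction`` ("increase" for the progesterone
    transient, "decrease" for the peptide dip).

    The default CI is the normal-theory 1.96 x SEM: that is the convention
    under which the criterion's type-I error approaches 0.05 when one
    sample is noiseless (see :mod:`catrace.alpha`).
    """
    trace = np.asarray(trace, dtype=float)
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    stim_idx = timebase.frame_of(stim_time_s)
    if stim_idx < n_pre:
        raise ValueError(
            f"only {stim_idx} pre-stimulus frames available; {n_pre} required"
        )
    pre = trace[stim_idx - n_pre: stim_idx]
    if search_window_s is None:
        search_window_s = (
            (0.0, PEAK_SEARCH_S) if direction == "increase" else (0.0, DIP_SEARCH_S)
        )
    win = _window_or_raise(
        timebase, stim_time_s + search_window_s[0], stim_time_s + search_window_s[1],
        "peak search",
    )
    vals = trace[win]
    rel = int(np.argmax(vals)) if direction == "increase" else int(np.argmin(vals))
    idx = int(win[rel])
    sel = np.arange(max(idx - 1, int(win[0])), min(idx + 1, int(win[-1])) + 1)
    peak_sample = trace[sel]

    pre_mean = float(pre.mean())
    peak_mean = float(peak_sample.mean())
    pre_ci = _ci95(pre, ci_convention)
    peak_ci = _ci95(peak_sample, ci_convention)
    diff = peak_mean - pre_mean
    right_sign = diff > 0 if direction == "increase" else diff < 0
    significant = bool(abs(diff) > pre_ci + peak_ci and right_sign)
    return DetectionVerdict(
        pre_mean=pre_mean,
        pre_ci95=pre_ci,
        peak_mean=peak_mean,
        peak_ci95=peak_ci,
        significant=significant,
        peak_time_s=float(timebase.times[idx] - stim_time_s),
    )


def classify_prolonged(
    trace: np.ndarray,
    timebase: TimeBase,
    stim_time_s: float,
    threshold: float = PROLONGED_THRESHOLD,
) -> bool:
    """Prolonged response: the 3-min amplitude is >= ``threshold`` x the
    peak amplitude (no discernible decay for at least 3 min).

    Intended for cells already classified as responders.
    """
    peak, _ = peak_amplitude(trace, timebase, stim_time_s)
    if not peak > 0:
        return False
    return bool(amplitude_at_3min(trace, timebase, stim_time_s) >= threshold * peak)


def detect_oscillations(
    trace: np.ndarray,
    timebase: TimeBase,
    analysis_window: np.ndarray | None = None,
    mad_factor: float = 3.0,
    min_events: int = 3,
) -> tuple[bool, np.ndarray]:
    """Detect spontaneous oscillatory events in a window of a dF trace.

    Events are local maxima exceeding ``median + mad_factor x scaled MAD``
    of the window, separated by at least 2 frames; the cell is flagged an
    oscillator when at least ``min_events`` events are found.

    The scaled MAD is computed one-sidedly, from the below-median
    deviations only: upward transients are the signal being detected, and
    letting them inflate the noise-scale estimate would suppress genuine
    events.  For symmetric noise the one-sided estimate is consistent for
    the same SD (half-normal median x 1.4826).

    Returns ``(flag, event_times_s)``.
    """
    trace = np.asarray(trace, dtype=float)
    if analysis_window is None:
        analysis_window = np.arange(timebase.n_frames)
    analysis_window = np.asarray(analysis_window, dtype=int)
    if analysis_window.size < 10:
        raise ValueError("oscillation analysis window must span >= 10 frames")
    vals = trace[analysis_window]
    med = float(np.median(vals))
    dev = vals - med
    mad = 1.4826 * float(np.median(np.abs(dev[dev <= 0])))
    thr = med + mad_factor * mad
    peaks, _ = sps.find_peaks(vals, height=thr, distance=2)
    event_times = timebase.times[analysis_window[peaks]]
    return bool(len(peaks) >= min_events), event_times


def oscillation_events_for_pause(
    trace: np.ndarray,
    timebase: TimeBase,
    baseline_window: np.ndarray,
    mad_factor: float = 3.0,
) -> np.ndarray:
    """Event times over the *whole* recording, for pause assessment.

    Uses a prominence criterion (``mad_factor`` x the scaled MAD of the
    pre-stimulus baseline window) rather than an absolute height, so that
    oscillatory events riding on the slow peptide-induced baseline dip are
    still counted — an absolute threshold would miss them and fake a pause.
    """
    trace = np.asarray(trace, dtype=float)
    vals = trace[np.asarray(baseline_window, dtype=int)]
    med = float(np.median(vals))
    dev = vals - med
    mad = 1.4826 * float(np.median(np.abs(dev[dev <= 0])))
    peaks, _ = sps.find_peaks(trace, prominence=mad_factor * mad, distance=2)
    return timebase.times[peaks]


def detect_pause(
    event_times: np.ndarray,
    peptide_time_s: float,
    factor: float = 2.0,
    guard_s: float = 0.0,
) -> bool | None:
    """Did oscillatory activity pause at peptide application?

    Pause iff the first inter-event interval containing or following the
    application exceeds ``factor`` x the median pre-application interval.
    Returns ``None`` (not assessable) with fewer than 3 pre-application
    events or no post-application event.

    ``guard_s`` handles sampling quantization: an event detected within
    ``guard_s`` of the application cannot be resolved as pre- or
    post-application at the frame rate, and is counted with the
    pre-application train (a sensible guard is ~1.5 frames).

    The baseline interval is a missed-event-robust median: intervals close
    to an integer multiple of the raw median (a single undetected event
    doubles an interval) are folded back by that multiple before the final
    median is taken.
    """
    times = np.sort(np.asarray(event_times, dtype=float))
    split = peptide_time_s + guard_s
    pre = times[times <= split]
    post = times[times > split]
    if len(pre) < 3 or len(post) == 0:
        return None
    intervals = np.diff(pre)
    m0 = float(np.median(intervals))
    folded = intervals / np.maximum(1, np.round(intervals / m0))
    baseline = float(np.median(folded))
    gap = float(post[0] - pre[-1])
    return bool(gap > factor * baseline)


def roi_synchrony(
    trace_phn: np.ndarray,
    trace_mid: np.ndarray,
    timebase: TimeBase,
    stim_time_s: float,
    max_lag_s: float = 120.0,
) -> float:
    """Lag (s) of the cross-correlation maximum between the post-stimulus
    PHN and midpiece dF segments of one cell.

    Positive lag means the PHN signal leads.  |lag| <= one frame is
    conventionally "simultaneous".  When the peak normalized correlation is
    below 0.5 the estimate is unreliable and a warning is issued.
    """
    a = np.asarray(trace_phn, dtype=float)
    b = np.asarray(trace_mid, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trace length mismatch: {a.shape} vs {b.shape}")
    start = timebase.frame_of(stim_time_s)
    a = a[start:] - a[start:].mean()
    b = b[start:] - b[start:].mean()
    n = len(a)
    c = np.correlate(a, b, mode="full")
    lags = np.arange(-(n - 1), n)
    max_lag = int(round(max_lag_s / timebase.sampling_interval_s))
    keep = np.abs(lags) <= max_lag
    c, lags = c[keep], lags[keep]
    k = int(np.argmax(c))
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    peak_corr = c[k] / denom if denom > 0 else 0.0
    if peak_corr < 0.5:
        warnings.warn(
            f"low peak cross-correlation ({peak_corr:.2f}); lag estimate is "
            f"unreliable",
            stacklevel=2,
        )
    # positive lag: PHN events occur earlier (PHN leads)
    return float(-lags[k] * timebase.sampling_interval_s)


def compute_cell_metrics(
    norm: NormalizedTraceSet,
    ci_convention: str = "normal_1.96",
    peak_from: str = "cell",
    prolonged_threshold: float = PROLONGED_THRESHOLD,
) -> pd.DataFrame:
    """Compute the full per-cell metrics table for one experiment.

    Uses the stimulus events recorded in the timebase: a ``progesterone``
    event drives the transient metrics (peak, 3-min amplitude, decay rate,
    S/T ratio, responder, prolonged) and a ``peptide`` event drives the dip
    detection and oscillation-pause assessment.  Oscillations are detected
    on the window preceding the first stimulus.

    ``peak_from="population"`` locates the peak frame on the experiment's
    R_tot trace and propagates it to every cell; the default locates the
    peak per cell.
    """
    tb = norm.timebase
    has_prog = tb.has_event("progesterone")
    has_pep = tb.has_event("peptide")
    t_prog = tb.event_time("progesterone") if has_prog else None
    t_pep = tb.event_time("peptide") if has_pep else None

    pop_window = None
    if has_prog and peak_from == "population":
        rtot = compute_rtot(norm).r_tot
        win = tb.window(t_prog, min(t_prog + PEAK_SEARCH_S, tb.duration_s))
        idx = int(win[np.argmax(rtot[win])])
        # fix the same three frames for every cell
        pop_window = np.arange(max(idx - 1, int(win[0])), min(idx + 1, int(win[-1])) + 1)
    elif peak_from not in ("cell", "population"):
        raise ValueError(f"peak_from must be 'cell' or 'population', got {peak_from!r}")

    first_event = min(t for _, t in tb.events) if tb.events else tb.duration_s
    osc_win = np.arange(tb.frame_of(first_event)) if tb.events else np.arange(tb.n_frames)

    rows = []
    for i, cid in enumerate(norm.cell_ids):
        tr = norm.dF[i]
        row: dict = {"cell_id": cid, "roi": norm.roi_labels[i]}
        if has_prog:
            if pop_window is not None:
                peak = float(tr[pop_window].mean())
                peak_t = float(tb.times[pop_window[len(pop_window) // 2]] - t_prog)
            else:
                peak, peak_t = peak_amplitude(tr, tb, t_prog)
            verdict = detect_responder(
                tr, tb, t_prog, direction="increase", ci_convention=ci_convention
            )
            row["peak_amp_pct"] = peak
            row["peak_time_s"] = peak_t
            row["responder"] = verdict.significant
            can_3min = tb.duration_s >= t_prog + 200.0
            row["amp_3min_pct"] = (
                amplitude_at_3min(tr, tb, t_prog) if can_3min else np.nan
            )
            row["decay_rate_pct_per_min"] = (
                decay_rate(tr, tb, t_prog) if tb.duration_s >= t_prog + 120.0 else np.nan
            )
            if verdict.significant and peak > 0 and tb.duration_s >= t_prog + 300.0:
                row["st_ratio"] = st_ratio(tr, tb, t_prog, peak)
            else:
                row["st_ratio"] = np.nan
            row["prolonged"] = bool(
                verdict.significant
                and can_3min
                and peak > 0
                and row["amp_3min_pct"] >= prolonged_threshold * peak
            )
        if len(osc_win) >= 10:
            osc_flag, events = detect_oscillations(tr, tb, osc_win)
            row["oscillator"] = osc_flag
            if has_pep and osc_flag:
                all_events = oscillation_events_for_pause(tr, tb, osc_win)
                row["paused_on_peptide"] = detect_pause(
                    all_events, t_pep, guard_s=1.5 * tb.sampling_interval_s
                )
        if has_pep:
            dip = detect_responder(
                tr, tb, t_pep, direction="decrease", ci_convention=ci_convention
            )
            row["dip_responder"] = dip.significant
            row["dip_amp_pct"] = dip.difference
        rows.append(row)
    return pd.DataFrame(rows)
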
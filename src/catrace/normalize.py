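"""Background correction, percent-change normalization, and the population
mean trace.

The normalized signal is the percent change in fluorescence

    dF = (F - F_rest) / F_rest * 100

where ``F_rest`` is the mean of at least 10 frames of the control period
(by default the 10 frames immediately preceding the first stimulus).  The
population readout of one experiment is ``R_tot``, the per-frame mean dF
over all its cells, with a per-frame SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExperimentDesign, RawTraceSet
from .timebase import TimeBase

__all__ = [
    "NormalizedTraceSet",
    "PopulationSummary",
    "background_correct",
    "default_control_window",
    "normalize",
    "compute_rtot",
]

MIN_CONTROL_FRAMES = 10


@dataclass
class NormalizedTraceSet:
    """dF (%) matrix with the control window used for F_rest.

    ``dropped_cells`` lists cells excluded because their resting
    fluorescence was non-positive (lost focus, detachment, empty ROI).
    """

    timebase: TimeBase
    dF: np.ndarray
    cell_ids: list[str]
    roi_labels: list[str]
    control_window: np.ndarray
    f_rest: np.ndarray
    design: ExperimentDesign | None = None
    dropped_cells: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.dF.shape[0]


@dataclass
class PopulationSummary:
    """R_tot: per-frame mean dF (%) over the cells of one experiment, +- SEM."""

    timebase: TimeBase
    r_tot: np.ndarray
    sem: np.ndarray
    n_cells: int
    arm: str = ""
    experiment_id: str = ""
    set_id: str = ""


def background_correct(raw: RawTraceSet) -> RawTraceSet:
    """Subtract the background (scalar or per-frame vector) from every trace.

    Negative corrected intensities are permitted with a warning — they occur
    when an ROI is dimmer than the chosen cell-free region.  The returned
    set has its background zeroed, so the operation is idempotent.
    """
    bg = np.asarray(raw.background, dtype=float)
    if bg.ndim not in (0, 1):
        raise ValueError("background must be a scalar or a per-frame vector")
    if bg.ndim == 1 and bg.shape[0] != raw.timebase.n_frames:
        raise ValueError(
            f"background vector length {bg.shape[0]} != n_frames "
            f"{raw.timebase.n_frames}"
        )
    corrected = raw.intensities - bg
    if np.any(corrected < 0):
        n_bad = int(np.sum((corrected < 0).any(axis=1)))
        warnings.warn(
            f"background correction produced negative intensities in "
            f"{n_bad} trace(s)",
            stacklevel=2,
        )
    return RawTraceSet(
        timebase=raw.timebase,
        intensities=corrected,
        cell_ids=list(raw.cell_ids),
        roi_labels=list(raw.roi_labels),
        background=0.0,
        design=raw.design,
    )


def default_control_window(timebase: TimeBase, n_frames: int = MIN_CONTROL_FRAMES) -> np.ndarray:
    """The ``n_frames`` frames immediately preceding the first stimulus event.

    With no events, the first ``n_frames`` frames of the recording.
    """
    if timebase.events:
        first = min(t for _, t in timebase.events)
        stop = timebase.frame_of(first)
    else:
        stop = timebase.n_frames
    start = stop - n_frames
    if start < 0:
        raise ValueError(
            f"recording has only {stop} pre-stimulus frames; "
            f"{n_frames} are required for F_rest"
        )
    return np.arange(start, stop)


def normalize(
    raw: RawTraceSet,
    control_window: np.ndarray | None = None,
    background_corrected: bool = False,
) -> NormalizedTraceSet:
    """Convert intensities to dF (%) relative to the control-period mean.

    ``control_window`` is an array of frame indices; it must contain at
    least 10 frames and must not extend past the first stimulus event.
    Cells whose F_rest is non-positive are dropped and reported in
    ``dropped_cells`` (and via a warning).
    """
    if not background_corrected:
        raw = background_correct(raw)
    if control_window is None:
        control_window = default_control_window(raw.timebase)
    control_window = np.asarray(control_window, dtype=int)
    if control_window.size < MIN_CONTROL_FRAMES:
        raise ValueError(
            f"control window has {control_window.size} frames; "
            f"at least {MIN_CONTROL_FRAMES} are required"
        )
    if control_window.min() < 0 or control_window.max() >= raw.timebase.n_frames:
        raise ValueError("control window outside the recording")
    if raw.timebase.events:
        first = min(t for _, t in raw.timebase.events)
        t_win = raw.timebase.times[control_window]
        if np.any(t_win > first):
            raise ValueError(
                f"control window extends past the first stimulus at {first} s"
            )

    f_rest = raw.intensities[:, control_window].mean(axis=1)
    keep = f_rest > 0
    dropped = [cid for cid, k in zip(raw.cell_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} cell(s) with non-positive resting "
            f"fluorescence: {dropped[:5]}",
            stacklevel=2,
        )
    F = raw.intensities[keep]
    fr = f_rest[keep]
    dF = (F - fr[:, None]) / fr[:, None] * 100.0
    return NormalizedTraceSet(
        timebase=raw.timebase,
        dF=dF,
        cell_ids=[c for c, k in zip(raw.cell_ids, keep) if k],
        roi_labels=[r for r, k in zip(raw.roi_labels, keep) if k],
        control_window=control_window,
        f_rest=fr,
        design=raw.design,
        dropped_cells=dropped,
    )


def compute_rtot(norm: NormalizedTraceSet) -> PopulationSummary:
    """Per-frame mean dF over cells (R_tot) and its SEM (sample SD / sqrt n).

    A single-cell experiment yields an all-zero SEM by convention, with a
    warning.
    """
    n = norm.n_cells
    if n < 1:
        raise ValueError("cannot summarize an empty trace set")
    r_tot = norm.dF.mean(axis=0)
    if n == 1:
        warnings.warn("single-cell experiment: SEM set to 0", stacklevel=2)
        sem = np.zeros_like(r_tot)
    else:
        sem = norm.dF.std(axis=0, ddof=1) / np.sqrt(n)
    d = norm.design
    return PopulationSummary(
        timebase=norm.timebase,
        r_tot=r_tot,
        sem=sem,
        n_cells=n,
        arm=d.arm if d else "",
        experiment_id=d.experiment_id if d else "",
        set_id=d.set_id if d else "",
    )
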
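"""Trace-matrix, ground-truth, metrics and config I/O.

File formats are deliberately plain: a trace set is a delimited-text matrix
whose first column is ``time_s`` and whose remaining columns are one cell
each (header row = cell IDs), with a JSON sidecar (``<path>.meta.json``)
holding everything a matrix cannot: stimulus events, ROI labels, background,
and the experiment design.  Readers validate rather than coerce: ragged rows,
non-uniform sampling and duplicate cell IDs are rejected with context.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .timebase import TimeBase

__all__ = [
    "ARMS",
    "ExperimentDesign",
    "RawTraceSet",
    "read_traceset",
    "write_traceset",
    "read_ground_truth",
    "write_ground_truth",
    "read_metrics",
    "write_metrics",
    "load_config",
    "save_config",
]

ARMS = ("control", "scrambled", "KIKKK")

#: stable column order for the per-cell metrics table
METRICS_COLUMNS = [
    "cell_id",
    "roi",
    "peak_amp_pct",
    "peak_time_s",
    "amp_3min_pct",
    "decay_rate_pct_per_min",
    "st_ratio",
    "responder",
    "prolonged",
    "oscillator",
    "paused_on_peptide",
]
_FLAG_COLUMNS = ("responder", "prolonged", "oscillator", "paused_on_peptide")


@dataclass(frozen=True)
class ExperimentDesign:
    """One imaging experiment: an arm of a parallel set plus stimulus times.

    ``set_id`` groups the three parallel arms (control / scrambled / KIKKK)
    of one experiment set; the working cell count per experiment in this kind
    of recording is a few tens of cells and is recorded but not enforced.
    """

    arm: str
    n_cells: int
    experiment_id: str
    set_id: str = ""
    peptide_time_s: float | None = None
    progesterone_time_s: float | None = None
    dual_roi: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")

    @property
    def stimulus_times(self) -> list[tuple[str, float]]:
        ev = []
        if self.peptide_time_s is not None:
            ev.append(("peptide", float(self.peptide_time_s)))
        if self.progesterone_time_s is not None:
            ev.append(("progesterone", float(self.progesterone_time_s)))
        return ev


@dataclass
class RawTraceSet:
    """Cells x frames fluorescence-intensity matrix (arbitrary units).

    ``background`` is either a scalar (mean of a cell-free region) or a
    per-frame vector; ``roi_labels`` records which region of interest each
    trace was drawn from (posterior head/neck ``"PHN"`` by default, or
    ``"midpiece"``).  A physical cell may contribute one trace per ROI,
    linked by a shared prefix of the cell ID.
    """

    timebase: TimeBase
    intensities: np.ndarray
    cell_ids: list[str]
    roi_labels: list[str] = field(default_factory=list)
    background: float | np.ndarray = 0.0
    design: ExperimentDesign | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D cells x frames matrix")
        n_cells, n_frames = self.intensities.shape
        if n_frames != self.timebase.n_frames:
            raise ValueError(
                f"matrix has {n_frames} frames but timebase has "
                f"{self.timebase.n_frames}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length must match the number of rows")
        dupes = pd.Index(self.cell_ids).duplicated()
        if dupes.any():
            bad = sorted({c for c, d in zip(self.cell_ids, dupes) if d})
            raise ValueError(f"duplicate cell IDs: {bad}")
        if not self.roi_labels:
            self.roi_labels = ["PHN"] * n_cells
        if len(self.roi_labels) != n_cells:
            raise ValueError("roi_labels length must match the number of rows")
        if np.ndim(self.background) == 1 and len(np.atleast_1d(self.background)) != n_frames:
            raise ValueError(
                f"per-frame background has length "
                f"{len(np.atleast_1d(self.background))}, expected {n_frames}"
            )

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]


def write_traceset(ts: RawTraceSet, path: str | Path) -> None:
    """Write a trace set as CSV (time_s + one column per cell) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(ts.intensities.T, columns=ts.cell_ids)
    df.insert(0, "time_s", ts.timebase.times)
    df.to_csv(path, index=False, float_format="%.10g")
    meta: dict = {
        "sampling_interval_s": ts.timebase.sampling_interval_s,
        "n_frames": ts.timebase.n_frames,
        "events": [[lab, t] for lab, t in ts.timebase.events],
        "roi_labels": list(ts.roi_labels),
        "background": (
            np.asarray(ts.background).tolist()
            if np.ndim(ts.background)
            else float(ts.background)
        ),
    }
    if ts.design is not None:
        meta["design"] = dataclasses.asdict(ts.design)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_traceset(path: str | Path) -> RawTraceSet:
    """Read a trace-set CSV written by :func:`write_traceset`.

    The sampling interval is inferred from the time column and checked
    uniform to 1e-6 relative tolerance.  Ragged rows, non-uniform sampling
    and duplicate cell IDs are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    dupes = pd.Index(header).duplicated()
    if dupes.any():
        bad = sorted({c for c, d in zip(header, dupes) if d})
        raise ValueError(f"{path}: duplicate cell IDs: {bad}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed trace matrix: {exc}") from exc
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing values in rows {rows[:5]}")
    cell_ids = list(df.columns[1:])
    dupes = pd.Index(cell_ids).duplicated()
    if dupes.any():
        bad = sorted({c for c, d in zip(cell_ids, dupes) if d})
        raise ValueError(f"{path}: duplicate cell IDs: {bad}")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column is not strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * abs(dt[0]):
            raise ValueError(f"{path}: non-uniform sampling interval in time column")
        interval = float(dt[0])
    else:
        interval = 10.0
    if abs(t[0]) > 1e-9 * max(1.0, interval):
        raise ValueError(f"{path}: time column must start at 0, got {t[0]}")

    events: tuple = ()
    roi_labels: list[str] = []
    background: float | np.ndarray = 0.0
    design = None
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        events = tuple((lab, float(tt)) for lab, tt in meta.get("events", []))
        roi_labels = list(meta.get("roi_labels", []))
        bg = meta.get("background", 0.0)
        background = np.asarray(bg, dtype=float) if isinstance(bg, list) else float(bg)
        if meta.get("design") is not None:
            design = ExperimentDesign(**meta["design"])
    tb = TimeBase(n_frames=len(t), sampling_interval_s=interval, events=events)
    return RawTraceSet(
        timebase=tb,
        intensities=df[cell_ids].to_numpy(float).T,
        cell_ids=cell_ids,
        roi_labels=roi_labels,
        background=background,
        design=design,
    )


def write_ground_truth(gt: pd.DataFrame, path: str | Path) -> None:
    """Ground-truth table keyed by cell ID, flags serialized as 0/1."""
    out = gt.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, float_format="%.10g")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    gt = pd.read_csv(path)
    for col in ("is_oscillator", "is_peptide_responder", "paused_on_peptide"):
        if col in gt.columns:
            gt[col] = gt[col].astype(bool)
    return gt


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell metrics table as CSV with a stable column order.

    Flags are serialized as 0/1; missing metrics become empty fields.  An
    empty table produces a header-only file.
    """
    out = metrics.copy()
    for col in METRICS_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    extra = [c for c in out.columns if c not in METRICS_COLUMNS]
    out = out[METRICS_COLUMNS + extra]
    for col in _FLAG_COLUMNS:
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else str(int(bool(v)))
        )
    out.to_csv(path, index=False, float_format="%.10g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(lambda v: bool(int(v)) if pd.notna(v) else pd.NA)
    return df


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=1, sort_keys=True))
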
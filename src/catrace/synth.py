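"""Synthetic single-cell calcium fluorescence cohorts with ground truth.

The generator emulates slow time-lapse (0.1 Hz) recordings of fluorescence
from individual cells, with the phenotype structure such recordings show:

* a subpopulation of spontaneous oscillators (repeated Ca transients under
  control conditions, optionally paused/reset by peptide application);
* a transient *dip* in resting signal after cell-penetrating-peptide
  application (minimum near +90 s, full recovery within 3-4 min, in roughly
  two thirds of cells);
* a biphasic progesterone response: a transient that peaks 15-30 s after
  stimulation and decays over 1-2 min onto a sustained plateau
  ("conventional" cells);
* a "prolonged" subpopulation whose transient holds at its peak for 3-10 min
  before decaying — the phenotype whose frequency differs between treatment
  arms (control / scrambled peptide / KIKKK peptide).

The trace model is additive in percent-change space: the true signal
``dF_true`` (in % of resting fluorescence) is the sum of independent
components, and the emitted intensity is

    F(t) = background + F0 * (1 + dF_true(t)/100) + Gaussian intensity noise

so the normalization stage can be tested against known truth.  All draws
flow from one integer seed; each cell has its own counter-derived substream,
so cell k's trace does not change when the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ARMS, ExperimentDesign, RawTraceSet
from .timebase import TimeBase

__all__ = [
    "PhenotypeParams",
    "generate_cohort",
    "make_progesterone_component",
    "make_peptide_dip_component",
    "make_oscillation_component",
    "peptide_experiment_timebase",
    "progesterone_experiment_timebase",
    "split_cells",
]

SUBTYPES = ("conventional", "prolonged", "nonresponder")


@dataclass(frozen=True)
class PhenotypeParams:
    """Phenotype frequencies and kinetic parameters of the synthetic cohort.

    Defaults are the study conditions the cohort emulates: arm-specific
    prolonged-response frequencies (control 8.8%, scrambled 6.3%, KIKKK
    15.2% of cells), ~65% of cells dipping on peptide with a population-mean
    dip of ~6.6%, ~19.2% spontaneous oscillators of which ~40% pause on
    peptide, and progesterone-responder fractions of 96-98.5%.  Plateau
    fractions are calibrated so the cohort-mean S/T ratio measured by the
    analysis pipeline reproduces 0.36 (control), 0.39 (scrambled) and 0.55
    (KIKKK); see docs/methods.md for the calibration.

    Ranges given as ``(lo, hi)`` tuples are sampled uniformly per cell.
    """

    # subpopulation frequencies
    p_oscillator: float = 0.192
    p_peptide_responder: float = 0.65
    p_progesterone_responder: dict = field(
        default_factory=lambda: {"control": 0.985, "scrambled": 0.961, "KIKKK": 0.959}
    )
    p_prolonged: dict = field(
        default_factory=lambda: {"control": 0.088, "scrambled": 0.063, "KIKKK": 0.152}
    )
    p_pause_on_peptide: dict = field(
        default_factory=lambda: {"control": 0.40, "scrambled": 0.398, "KIKKK": 0.428}
    )

    # peptide-induced dip kinetics (per responding cell, % dF)
    dip_amplitude_pct: float = 10.2  # 0.65 responders * 10.2% ~= 6.6% population dip
    dip_amplitude_sd_pct: float = 3.5
    dip_tmin_s: float = 90.0
    dip_recovery_s: tuple = (180.0, 240.0)

    # progesterone transient kinetics
    transient_peak_t_s: tuple = (15.0, 30.0)  # time-to-peak (rise time)
    transient_decay_tau_s: tuple = (20.0, 40.0)  # decay to plateau within 1-2 min
    peak_amp_mean_pct: float = 50.0
    peak_amp_sd_pct: float = 15.0
    peak_amp_bounds_pct: tuple = (15.0, 120.0)
    plateau_fraction_mean: dict = field(
        default_factory=lambda: {"control": 0.225, "scrambled": 0.269, "KIKKK": 0.385}
    )
    plateau_fraction_sd: float = 0.12
    plateau_fraction_bounds: tuple = (0.02, 0.65)
    prolonged_hold_min: tuple = (3.0, 10.0)

    # spontaneous oscillations
    oscillation_period_s: float = 100.0
    oscillation_amplitude_pct: float = 20.0
    oscillation_decay_tau_s: float = 15.0
    oscillation_jitter_frac: float = 0.03
    pause_stretch: float = 2.5  # paused inter-event interval, in periods

    # measurement model
    noise_sd_pct: float = 2.0
    baseline_intensity_mean: float = 1000.0
    baseline_intensity_sd: float = 150.0
    baseline_intensity_bounds: tuple = (300.0, 3000.0)
    background_au: float = 100.0
    drift_pct_per_min: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            "p_oscillator": self.p_oscillator,
            "p_peptide_responder": self.p_peptide_responder,
            **{f"p_progesterone_responder[{a}]": v for a, v in self.p_progesterone_responder.items()},
            **{f"p_prolonged[{a}]": v for a, v in self.p_prolonged.items()},
            **{f"p_pause_on_peptide[{a}]": v for a, v in self.p_pause_on_peptide.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("dip_tmin_s", "oscillation_period_s", "oscillation_decay_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "dip_amplitude_pct",
            "dip_amplitude_sd_pct",
            "peak_amp_mean_pct",
            "noise_sd_pct",
            "oscillation_amplitude_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "PhenotypeParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeParams":
        d = dict(d)
        for key in ("dip_recovery_s", "transient_peak_t_s", "transient_decay_tau_s",
                    "peak_amp_bounds_pct", "plateau_fraction_bounds", "prolonged_hold_min",
                    "baseline_intensity_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _uniform(rng: np.random.Generator, rng_tuple) -> float:
    lo, hi = rng_tuple
    if hi < lo:
        raise ValueError(f"invalid range {rng_tuple}")
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _check_event(timebase: TimeBase, time_s: float, what: str) -> None:
    if not 0 <= time_s <= timebase.duration_s:
        raise ValueError(
            f"{what} at t={time_s} s lies outside the recording "
            f"[0, {timebase.duration_s}] s"
        )


# ---------------------------------------------------------------------------
# waveform components (all return per-frame additive dF signals, in %)

def draw_progesterone_kinetics(
    subtype: str, params: PhenotypeParams, rng: np.random.Generator, arm: str = "control"
) -> dict:
    """Draw the per-cell kinetic parameters of the progesterone response.

    The draw order is fixed so that cohort generation is reproducible.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"subtype must be one of {SUBTYPES}, got {subtype!r}")
    k = {
        "peak_pct": _truncnorm(
            rng, params.peak_amp_mean_pct, params.peak_amp_sd_pct,
            *params.peak_amp_bounds_pct,
        ),
        "rise_s": _uniform(rng, params.transient_peak_t_s),
        "tau_s": _uniform(rng, params.transient_decay_tau_s),
        "plateau_fraction": _truncnorm(
            rng, params.plateau_fraction_mean[arm], params.plateau_fraction_sd,
            *params.plateau_fraction_bounds,
        ),
        "hold_s": 60.0 * _uniform(rng, params.prolonged_hold_min),
    }
    return k


def progesterone_waveform(t_rel: np.ndarray, subtype: str, kin: dict) -> np.ndarray:
    """Noise-free progesterone-response waveform at times ``t_rel`` (s after stim)."""
    t_rel = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t_rel)
    if subtype == "nonresponder":
        return out
    peak, rise, tau, pf = (
        kin["peak_pct"], kin["rise_s"], kin["tau_s"], kin["plateau_fraction"],
    )
    # linear rise to the peak
    m = (t_rel >= 0) & (t_rel <= rise)
    out[m] = peak * t_rel[m] / rise
    # decay starts at the end of the rise (conventional) or of the hold (prolonged)
    decay_from = max(kin["hold_s"], rise) if subtype == "prolonged" else rise
    m = (t_rel > rise) & (t_rel <= decay_from)
    out[m] = peak
    m = t_rel > decay_from
    out[m] = peak * (pf + (1.0 - pf) * np.exp(-(t_rel[m] - decay_from) / tau))
    return out


def make_progesterone_component(
    subtype: str,
    params: PhenotypeParams,
    timebase: TimeBase,
    stim_time_s: float,
    rng: np.random.Generator,
    arm: str = "control",
    kinetics: dict | None = None,
) -> np.ndarray:
    """Additive progesterone-response signal (% dF), zero before the stimulus.

    Conventional cells rise to a peak and decay exponentially onto a plateau
    at ``plateau_fraction`` of the peak; prolonged cells hold the peak for
    3-10 min (measured from stimulation) before the same decay; nonresponders
    contribute zeros.
    """
    _check_event(timebase, stim_time_s, "progesterone stimulus")
    if subtype not in SUBTYPES:
        raise ValueError(f"subtype must be one of {SUBTYPES}, got {subtype!r}")
    if kinetics is None:
        kinetics = draw_progesterone_kinetics(subtype, params, rng, arm)
    return progesterone_waveform(timebase.times - stim_time_s, subtype, kinetics)


def make_peptide_dip_component(
    params: PhenotypeParams,
    timebase: TimeBase,
    app_time_s: float,
    rng: np.random.Generator,
    depth_pct: float | None = None,
) -> np.ndarray:
    """Additive peptide-dip signal (% dF): non-positive, V-shaped.

    Linear fall to ``-depth`` at ``app + dip_tmin_s`` and linear recovery to
    zero by ``app + recovery`` (recovery drawn uniformly per cell).
    """
    _check_event(timebase, app_time_s, "peptide application")
    if depth_pct is None:
        if params.dip_amplitude_pct == 0:
            depth_pct = 0.0
        else:
            depth_pct = _truncnorm(
                rng, params.dip_amplitude_pct, params.dip_amplitude_sd_pct,
                0.0, 4.0 * params.dip_amplitude_pct,
            )
    recovery = _uniform(rng, params.dip_recovery_s)
    if recovery <= params.dip_tmin_s:
        raise ValueError("dip_recovery_s must exceed dip_tmin_s")
    t_rel = timebase.times - app_time_s
    out = np.zeros_like(t_rel)
    m = (t_rel >= 0) & (t_rel <= params.dip_tmin_s)
    out[m] = -depth_pct * t_rel[m] / params.dip_tmin_s
    m = (t_rel > params.dip_tmin_s) & (t_rel < recovery)
    out[m] = -depth_pct * (recovery - t_rel[m]) / (recovery - params.dip_tmin_s)
    return out


def make_oscillation_component(
    params: PhenotypeParams,
    timebase: TimeBase,
    rng: np.random.Generator,
    pause_event_s: float | None = None,
) -> np.ndarray:
    """Additive spontaneous-oscillation signal (% dF).

    A train of spike-like transients (instant rise, exponential decay with
    ``oscillation_decay_tau_s``) at roughly the configured period.  When
    ``pause_event_s`` is given, the first inter-event interval after that
    time is stretched to ``pause_stretch`` periods (arrest + reset); the
    amplitude and period afterwards are unchanged.
    """
    period = params.oscillation_period_s
    if period < 2 * timebase.sampling_interval_s:
        raise ValueError(
            f"oscillation period {period} s is under-sampled at "
            f"{timebase.sampling_interval_s} s/frame"
        )
    amp = params.oscillation_amplitude_pct
    out = np.zeros(timebase.n_frames)
    # event times are always drawn (even for amp=0) to keep streams aligned
    t_event = float(rng.uniform(0, period))
    events = []
    paused = False
    while t_event <= timebase.duration_s:
        if pause_event_s is not None and not paused and t_event > pause_event_s:
            # arrest: lengthen this one interval, then resume unchanged
            t_event += (params.pause_stretch - 1.0) * period
            paused = True
            if t_event > timebase.duration_s:
                break
        events.append(t_event)
        jitter = 1.0 + params.oscillation_jitter_frac * float(rng.standard_normal())
        t_event += period * max(jitter, 0.1)
    if amp == 0:
        return out
    t = timebase.times
    for te in events:
        m = t >= te
        out[m] += amp * np.exp(-(t[m] - te) / params.oscillation_decay_tau_s)
    return out


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(
    design: ExperimentDesign,
    params: PhenotypeParams,
    timebase: TimeBase,
    seed: int,
) -> tuple[RawTraceSet, pd.DataFrame]:
    """Generate one experiment's cohort of traces plus per-cell ground truth.

    Returns a :class:`RawTraceSet` (intensities in arbitrary units, with
    background and design recorded) and a ground-truth DataFrame aligned
    row-for-row with the traces.  The noise-free true dF matrix (in %) is
    attached as ``ground_truth.attrs["dF_true"]`` for recovery testing.

    Identical ``(design, params, timebase, seed)`` reproduce identical
    output; each cell draws from its own seed-derived substream.
    """
    for label, t in design.stimulus_times:
        _check_event(timebase, t, f"{label} event")
    arm = design.arm
    n = design.n_cells
    rois = ("PHN", "midpiece") if design.dual_roi else ("PHN",)

    intensities = []
    dF_true_rows = []
    rows = []
    cell_ids = []
    roi_labels = []
    for i in range(n):
        rng = np.random.default_rng([int(seed) % (2**31), i])
        # fixed draw order: phenotype flags, then kinetics, then noise
        is_osc = bool(rng.random() < params.p_oscillator)
        pauses = bool(rng.random() < params.p_pause_on_peptide[arm])
        is_pep = bool(rng.random() < params.p_peptide_responder)
        p_resp = params.p_progesterone_responder[arm]
        is_resp = bool(rng.random() < p_resp)
        p_prol_given_resp = params.p_prolonged[arm] / p_resp if p_resp > 0 else 0.0
        if p_prol_given_resp > 1:
            raise ValueError(
                f"p_prolonged[{arm}] exceeds p_progesterone_responder[{arm}]"
            )
        subtype = (
            "nonresponder" if not is_resp
            else ("prolonged" if rng.random() < p_prol_given_resp else "conventional")
        )
        kin = draw_progesterone_kinetics(subtype, params, rng, arm)

        dF = np.zeros(timebase.n_frames)
        if design.peptide_time_s is not None and is_pep:
            dF = dF + make_peptide_dip_component(
                params, timebase, design.peptide_time_s, rng
            )
        true_st = np.nan
        if design.progesterone_time_s is not None and subtype != "nonresponder":
            comp = progesterone_waveform(
                timebase.times - design.progesterone_time_s, subtype, kin
            )
            dF = dF + comp
            st_win = timebase.window(
                design.progesterone_time_s + 180, design.progesterone_time_s + 300
            )
            if len(st_win):
                true_st = float(comp[st_win].mean() / kin["peak_pct"])
        if is_osc:
            pause_at = design.peptide_time_s if pauses else None
            dF = dF + make_oscillation_component(params, timebase, rng, pause_at)
        if params.drift_pct_per_min:
            dF = dF + params.drift_pct_per_min * timebase.times / 60.0

        f0 = _truncnorm(
            rng, params.baseline_intensity_mean, params.baseline_intensity_sd,
            *params.baseline_intensity_bounds,
        )
        for roi in rois:
            noise = (
                rng.standard_normal(timebase.n_frames) * params.noise_sd_pct / 100.0 * f0
                if params.noise_sd_pct > 0
                else np.zeros(timebase.n_frames)
            )
            trace = params.background_au + f0 * (1.0 + dF / 100.0) + noise
            cid = f"{design.experiment_id}_c{i:04d}" + ("" if roi == "PHN" else "_mid")
            cell_ids.append(cid)
            roi_labels.append(roi)
            intensities.append(trace)
            dF_true_rows.append(dF)
            rows.append(
                {
                    "cell_id": cid,
                    "roi": roi,
                    "is_oscillator": is_osc,
                    "is_peptide_responder": is_pep,
                    "response_subtype": subtype,
                    "true_st_ratio": true_st,
                    "true_peak_pct": kin["peak_pct"] if subtype != "nonresponder" else 0.0,
                    "paused_on_peptide": bool(is_osc and pauses),
                }
            )

    ts = RawTraceSet(
        timebase=timebase,
        intensities=np.asarray(intensities),
        cell_ids=cell_ids,
        roi_labels=roi_labels,
        background=params.background_au,
        design=design,
    )
    gt = pd.DataFrame(rows)
    gt.attrs["dF_true"] = np.asarray(dF_true_rows)
    return ts, gt


# ---------------------------------------------------------------------------
# canonical experiment layouts

def peptide_experiment_timebase(
    app_time_s: float = 400.0, post_s: float = 300.0, sampling_interval_s: float = 10.0
) -> TimeBase:
    """Peptide-application recording: long pre-stimulus baseline (default
    400 s, enough to observe spontaneous oscillations), dip and recovery."""
    n = int(round((app_time_s + post_s) / sampling_interval_s)) + 1
    return TimeBase(n, sampling_interval_s, (("peptide", app_time_s),))


def progesterone_experiment_timebase(
    stim_time_s: float = 200.0, post_s: float = 720.0, sampling_interval_s: float = 10.0
) -> TimeBase:
    """Progesterone-stimulation recording: baseline, transient, and enough
    tail (default 12 min post-stimulus) to measure the 3-5 min sustained
    window and prolonged plateaus."""
    n = int(round((stim_time_s + post_s) / sampling_interval_s)) + 1
    return TimeBase(n, sampling_interval_s, (("progesterone", stim_time_s),))


def split_cells(total: int, n_experiments: int) -> list[int]:
    """Balanced split of a cohort total over experiments (e.g. 424 over 9)."""
    if total < n_experiments:
        raise ValueError("need at least one cell per experiment")
    base = total // n_experiments
    extra = total % n_experiments
    return [base + (1 if i < extra else 0) for i in range(n_experiments)]
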
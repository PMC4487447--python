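"""Windowed metrics against brute-force oracles, the CI-sum criterion on
constructed samples, detectors, and ground-truth recovery on labelled
synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import catrace as ct
from catrace.metrics import oscillation_events_for_pause
from catrace.synth import progesterone_waveform

TB = ct.TimeBase(n_frames=60)  # 0..590 s
STIM = 200.0


def trace_with(values_from_stim):
    tr = np.zeros(TB.n_frames)
    i0 = TB.frame_of(STIM)
    tr[i0: i0 + len(values_from_stim)] = values_from_stim
    return tr


# -------------------------------------------------------------- peak amplitude

def test_peak_amplitude_is_mean_of_three_frames_spanning_peak():
    tr = trace_with([0, 2, 8, 10, 9, 4, 1])
    amp, t_peak = ct.peak_amplitude(tr, TB, STIM)
    assert amp == pytest.approx((8 + 10 + 9) / 3)
    assert t_peak == 30.0


def test_flat_trace_peak_is_zero_at_first_window_frame():
    amp, t_peak = ct.peak_amplitude(np.zeros(TB.n_frames), TB, STIM)
    assert amp == 0.0
    assert t_peak == 0.0  # tie broken toward the earliest frame


def test_peak_window_outside_recording_rejected():
    with pytest.raises(ValueError):
        ct.peak_amplitude(np.zeros(TB.n_frames), TB, 550.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_peak_amplitude_matches_brute_force_oracle(seed):
    r = np.random.default_rng(seed)
    tr = r.normal(0, 5, TB.n_frames)
    amp, t_peak = ct.peak_amplitude(tr, TB, STIM)
    # oracle: exhaustive argmax then mean of up to three spanning frames
    win = [i for i in range(TB.n_frames) if STIM <= TB.times[i] <= STIM + 120]
    best = max(win, key=lambda i: tr[i])
    span = [i for i in (best - 1, best, best + 1) if win[0] <= i <= win[-1]]
    assert amp == pytest.approx(np.mean([tr[i] for i in span]))
    assert t_peak == TB.times[best] - STIM


# ------------------------------------------------------------- 3-min amplitude

def test_amp_3min_of_constant_trace():
    tr = trace_with([42.0] * 40)
    assert ct.amplitude_at_3min(tr, TB, STIM) == pytest.approx(42.0)
    assert ct.amplitude_at_3min(np.zeros(TB.n_frames), TB, STIM) == 0.0


def test_amp_3min_linear_ramp_uses_frames_150_to_200():
    tr = TB.times / 10.0  # dF(t) = t/10
    expected = np.mean([(STIM + s) / 10.0 for s in (150, 160, 170, 180, 190, 200)])
    assert ct.amplitude_at_3min(tr, TB, STIM) == pytest.approx(expected)


def test_amp_3min_requires_long_enough_recording():
    with pytest.raises(ValueError):
        ct.amplitude_at_3min(np.zeros(TB.n_frames), TB, 450.0)


# ----------------------------------------------------------------- decay rate

def test_decay_rate_of_linear_decline_is_minus_ten():
    tr = -10.0 * (TB.times - STIM) / 60.0  # 10% per minute down
    assert ct.decay_rate(tr, TB, STIM) == pytest.approx(-10.0)


def test_decay_rate_of_plateau_is_zero():
    assert ct.decay_rate(np.full(TB.n_frames, 30.0), TB, STIM) == pytest.approx(0.0, abs=1e-9)


def test_decay_rate_matches_closed_form_least_squares():
    tau = 45.0
    tr = 50.0 * np.exp(-np.clip(TB.times - STIM, 0, None) / tau)
    got = ct.decay_rate(tr, TB, STIM)
    # closed-form simple regression on the four frames at stim+90..120 s
    idx = [i for i in range(TB.n_frames) if STIM + 90 <= TB.times[i] <= STIM + 120]
    x = TB.times[idx] / 60.0
    y = tr[idx]
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert got == pytest.approx(slope, rel=1e-12)


# ------------------------------------------------------------------ S/T ratio

def test_st_ratio_of_perfect_plateau_is_one():
    tr = trace_with([42.0] * 40)
    peak, _ = ct.peak_amplitude(tr, TB, STIM)
    assert ct.st_ratio(tr, TB, STIM, peak) == pytest.approx(1.0)
    assert ct.classify_prolonged(tr, TB, STIM)


def test_st_ratio_of_fully_decayed_transient_is_zero():
    tr = trace_with([0, 50, 50, 50, 0, 0])  # gone well before 3 min
    peak, _ = ct.peak_amplitude(tr, TB, STIM)
    assert ct.st_ratio(tr, TB, STIM, peak) == pytest.approx(0.0)
    assert not ct.classify_prolonged(tr, TB, STIM)


def test_st_ratio_undefined_for_nonpositive_peak():
    assert np.isnan(ct.st_ratio(np.zeros(TB.n_frames), TB, STIM, 0.0))


def test_st_ratio_of_conventional_waveform_matches_analytic_value():
    kin = {"peak_pct": 50.0, "rise_s": 20.0, "tau_s": 40.0,
           "plateau_fraction": 0.3, "hold_s": 240.0}
    tr = progesterone_waveform(TB.times - STIM, "conventional", kin)
    peak, _ = ct.peak_amplitude(tr, TB, STIM)
    got = ct.st_ratio(tr, TB, STIM, peak)
    # analytic: window mean of the closed-form waveform over +180..+300 s
    t = np.array([180, 190, 200, 210, 220, 230, 240, 250, 260, 270, 280, 290, 300.0])
    wave = 50.0 * (0.3 + 0.7 * np.exp(-(t - 20.0) / 40.0))
    assert got == pytest.approx(wave.mean() / peak, rel=1e-12)


# ----------------------------------------------------------- CI-sum criterion

def _pre_block(mean, sem):
    # ten points with exact mean and SEM: alternating +-3*sem around mean
    return mean + sem * np.array([3.0, -3.0] * 5)


def _peak_block(mean, sem):
    # three points with exact mean and SEM: sd = sem*sqrt(3)
    x = sem * np.sqrt(3.0)
    return np.array([mean + x, mean, mean - x])


def _criterion_trace(pre, peak):
    tr = np.zeros(TB.n_frames)
    i0 = TB.frame_of(STIM)
    tr[i0 - 10: i0] = pre
    # place the peak triplet so argmax+-1 selects exactly these three values
    tr[i0 + 1] = peak[2]
    tr[i0 + 2] = peak[0]
    tr[i0 + 3] = peak[1]
    return tr


def test_identical_pre_and_peak_not_significant():
    tr = np.zeros(TB.n_frames)
    verdict = ct.detect_responder(tr, TB, STIM)
    assert not verdict.significant


def test_criterion_rejects_when_difference_exceeds_ci_sum():
    """pre: mean 0, SEM 1; peak: mean 5, SEM 1 -> |5| > 1.96*(1+1)."""
    tr = _criterion_trace(_pre_block(0.0, 1.0), _peak_block(5.0, 1.0))
    verdict = ct.detect_responder(tr, TB, STIM)
    assert verdict.pre_ci95 == pytest.approx(1.96)
    assert verdict.peak_ci95 == pytest.approx(1.96)
    assert verdict.significant


def test_criterion_accepts_null_when_difference_below_ci_sum():
    """pre: mean 0, SEM 1; peak: mean 3, SEM 1 -> 3 < 3.92."""
    tr = _criterion_trace(_pre_block(0.0, 1.0), _peak_block(3.0, 1.0))
    assert not ct.detect_responder(tr, TB, STIM).significant


def test_criterion_requires_matching_direction():
    tr = _criterion_trace(_pre_block(0.0, 1.0), _peak_block(5.0, 1.0))
    assert not ct.detect_responder(tr, TB, STIM, direction="decrease").significant


def test_criterion_invariant_under_additive_offset():
    tr = _criterion_trace(_pre_block(0.0, 1.0), _peak_block(5.0, 1.0))
    v1 = ct.detect_responder(tr, TB, STIM)
    v2 = ct.detect_responder(tr + 123.4, TB, STIM)
    assert v1.significant == v2.significant
    assert v1.difference == pytest.approx(v2.difference)


def test_criterion_needs_ten_pre_frames():
    tb = ct.TimeBase(n_frames=30)
    with pytest.raises(ValueError, match="pre-stimulus"):
        ct.detect_responder(np.zeros(30), tb, 50.0)


# ----------------------------------------------------------------- prolonged

def test_prolonged_classification_from_waveforms():
    prol = {"peak_pct": 50.0, "rise_s": 20.0, "tau_s": 30.0,
            "plateau_fraction": 0.3, "hold_s": 240.0}
    conv = dict(prol, hold_s=0.0)
    tr_p = progesterone_waveform(TB.times - STIM, "prolonged", prol)
    tr_c = progesterone_waveform(TB.times - STIM, "conventional", conv)
    assert ct.classify_prolonged(tr_p, TB, STIM)
    assert not ct.classify_prolonged(tr_c, TB, STIM)


def test_subtype_recovery_on_labelled_cohort(control_cohort):
    """Responder detection and prolonged classification agree with the
    generator's labels on >= 95% of cells at default noise."""
    _, gt, norm = control_cohort
    met = ct.compute_cell_metrics(norm)
    truth_prol = (gt["response_subtype"] == "prolonged").to_numpy()
    truth_resp = (gt["response_subtype"] != "nonresponder").to_numpy()
    pred_prol = met["prolonged"].to_numpy(bool)
    pred_resp = met["responder"].to_numpy(bool)
    subtype_agree = np.mean(
        (pred_prol == truth_prol) & (pred_resp == truth_resp)
    )
    assert subtype_agree >= 0.95
    # responder sensitivity for true progesterone responders
    assert pred_resp[truth_resp].mean() >= 0.95


# --------------------------------------------------------------- oscillations

def test_flat_trace_has_no_oscillation_events():
    flag, events = ct.detect_oscillations(np.zeros(50), ct.TimeBase(50))
    assert not flag and len(events) == 0


def test_oscillator_with_five_periods_detected(default_params):
    tb = ct.TimeBase(n_frames=55)  # 540 s: five 100 s periods + margin
    p = default_params.replace(oscillation_jitter_frac=0.0)
    sig = ct.make_oscillation_component(p, tb, np.random.default_rng(1))
    flag, events = ct.detect_oscillations(sig, tb)
    assert flag
    assert 4 <= len(events) <= 6
    assert np.allclose(np.diff(events), 100.0, atol=10.0)


def test_subthreshold_ripple_not_flagged():
    tb = ct.TimeBase(n_frames=50)
    r = np.random.default_rng(0)
    sig = r.normal(0, 2.0, 50)  # pure noise, no transients
    flag, _ = ct.detect_oscillations(sig, tb)
    assert not flag


def test_too_short_window_rejected():
    with pytest.raises(ValueError):
        ct.detect_oscillations(np.zeros(50), ct.TimeBase(50), np.arange(5))


# ---------------------------------------------------------------------- pause

def test_regular_events_are_not_a_pause():
    events = np.arange(50.0, 900.0, 100.0)
    assert ct.detect_pause(events, 400.0) is False


def test_stretched_interval_is_a_pause():
    events = np.array([50.0, 150.0, 250.0, 350.0, 600.0, 700.0])
    assert ct.detect_pause(events, 400.0) is True


def test_pause_not_assessable_with_few_events():
    assert ct.detect_pause(np.array([100.0, 700.0]), 400.0) is None


def test_pause_recovery_on_labelled_cohorts(default_params, pep_tb):
    """Pause detection agrees with the generator's labels on >= 90% of
    detected oscillators across 20 seeded experiments at default noise."""
    agree = total = 0
    for j in range(20):
        design = ct.ExperimentDesign(
            arm="KIKKK", n_cells=50, experiment_id=f"p{j}", peptide_time_s=400.0
        )
        ts, gt = ct.generate_cohort(design, default_params, pep_tb, seed=4000 + j)
        met = ct.compute_cell_metrics(ct.normalize(ts))
        mask = gt["is_oscillator"].to_numpy(bool) & met["oscillator"].to_numpy(bool)
        for det, tru in zip(met.loc[mask, "paused_on_peptide"],
                            gt.loc[mask, "paused_on_peptide"]):
            if det is None or (isinstance(det, float) and np.isnan(det)):
                continue
            total += 1
            agree += bool(det) == bool(tru)
    assert total > 50
    assert agree / total >= 0.90


# ------------------------------------------------------------------ synchrony

def test_identical_roi_traces_have_zero_lag():
    tr = progesterone_waveform(
        TB.times - STIM, "conventional",
        {"peak_pct": 50.0, "rise_s": 20.0, "tau_s": 40.0,
         "plateau_fraction": 0.3, "hold_s": 0.0},
    )
    assert ct.roi_synchrony(tr, tr, TB, STIM) == 0.0


def test_two_frame_shift_gives_plus_twenty_seconds_phn_leading():
    tb = ct.progesterone_experiment_timebase()
    sig = np.exp(-np.clip(tb.times - 220.0, 0, None) / 60.0) * (tb.times >= 220.0) * 50
    mid = np.roll(sig, 2)  # midpiece lags by two frames
    assert ct.roi_synchrony(sig, mid, tb, 200.0) == pytest.approx(20.0)
    assert ct.roi_synchrony(mid, sig, tb, 200.0) == pytest.approx(-20.0)


def test_uncorrelated_noise_warns_low_confidence():
    r = np.random.default_rng(3)
    with pytest.warns(UserWarning, match="low peak cross-correlation"):
        ct.roi_synchrony(r.normal(size=TB.n_frames), r.normal(size=TB.n_frames), TB, STIM)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        ct.roi_synchrony(np.zeros(10), np.zeros(12), TB, STIM)


# ------------------------------------------------------------- metrics table

def test_compute_cell_metrics_population_peak_mode(control_cohort):
    _, _, norm = control_cohort
    met_cell = ct.compute_cell_metrics(norm, peak_from="cell")
    met_pop = ct.compute_cell_metrics(norm, peak_from="population")
    # population mode fixes one peak time for every cell
    assert met_pop["peak_time_s"].nunique() == 1
    assert met_cell["peak_time_s"].nunique() > 1
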
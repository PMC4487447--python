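# Methods

## The measurement model

Recordings are slow time-lapse fluorescence series: one frame every 10 s
(0.1 Hz), one region of interest (ROI) per cell — by default the posterior
head/neck (PHN) of a sperm cell, optionally a second midpiece ROI linked by
cell ID.  Intensities are arbitrary camera units.  Analysis begins from a
cells × frames matrix; pixel-level image processing is out of scope.

Normalization is the standard percent-change transform

    dF(t) = (F(t) − F_rest) / F_rest × 100 ,

with `F_rest` the mean of at least 10 frames of the control period.  The
default control window is the 10 frames immediately preceding the first
stimulus, which matches the pre-stimulus sample used by the response
criterion; the window is configurable but may not extend past the first
stimulus, and must contain at least 10 frames.  Background is subtracted
first — a scalar (mean of a cell-free region) or a per-frame vector; cells
whose resting fluorescence is non-positive (lost focus, detachment) are
dropped and reported, not imputed.  SEMs everywhere use the n−1 sample SD.
No detrending, bleaching correction, or filtering is applied.

The population readout of one experiment is `R_tot(t)`, the per-frame mean
dF over all its cells, with per-frame SEM.

## Windowed response metrics

All post-stimulus windows are defined in seconds and resolved to frames by
nearest-frame rounding (exact half-frame ties go to the earlier frame):

| metric | definition | frames at 0.1 Hz |
|---|---|---|
| peak amplitude | mean of the 3 frames spanning the argmax in (stim, stim+120 s] | argmax ± 1, truncated at window edges |
| 3-min amplitude | mean of 6 consecutive frames spanning 2.5–3.5 min | +150…+200 s |
| decay rate | least-squares slope over 1.5–2 min, % per minute | 4 frames, +90…+120 s |
| S/T ratio | mean dF over 3–5 min ÷ peak amplitude | 13 frames, +180…+300 s |
| early sustained (R_tot summaries) | mean R_tot over 2.5–3.3 min | 5 frames, +150…+198 s |

The S/T ratio is not clamped; plateau cells can exceed 1 slightly because
the 3-point peak mean under-estimates the true peak of a sampled transient.
The peak can be located per cell (default) or propagated to all cells from
the experiment's `R_tot` argmax (`peak_from="population"`); the dip search
window after peptide application is (app, app+180 s].

**Prolonged responses** ("no discernible decay for ≥3 min") are
operationalized quantitatively: a responder is prolonged when its 3-min
amplitude is at least 0.9 × its peak amplitude.  The 0.9 threshold
coincides with the S/T histogram shoulder (ratios > 0.9) that marks plateau
cells.

## The CI-sum response criterion and its type-I error

A cell (or an `R_tot` trace) responds significantly when

    |mean(peak 3 frames) − mean(pre 10 frames)| > CI95_pre + CI95_peak ,

with the sign of the difference matching the queried direction (increase
for progesterone, decrease for the peptide dip).  The default CI convention
is normal-theory, CI95 = 1.96 × SEM; this is the convention under which the
criterion's null behaviour has a clean closed form.  A t-based convention
(t₀.₉₇₅,df × SEM) is available for sensitivity analysis.

With the two SEMs treated as known and the errors Gaussian, the null
rejection probability depends only on the SEM ratio r = SEM_peak/SEM_pre:

    alpha(r) = 2 (1 − Φ(1.96 (1+r) / √(1+r²))) ,

which is 0.05 at r = 0 (one sample noiseless — the criterion degenerates to
an ordinary two-sided 1.96-SEM test), symmetric under r ↔ 1/r, and minimal
at r = 1 (equal SEMs), where alpha = 0.0056.  The Monte-Carlo simulator
(`catrace.alpha`) reproduces this curve in known-SEM mode; every grid point
agrees with the closed form within 3 Monte-Carlo SE.

**A caveat worth knowing.**  In practice the criterion estimates both SEMs
from the samples.  With only 3 peak points the SEM estimate has 2 degrees
of freedom and a heavy left tail, so the estimated threshold is often far
too small; simulation shows the equal-SEM alpha rises from 0.0056 to ≈0.03.
Estimation therefore makes the criterion markedly *less* stringent than
the normal-theory analysis suggests — the often-quoted stringency of
"sum-of-CI" overlap rules holds for known SEMs only.  Using t-quantiles
with the estimated SEMs restores stringency (alpha ≈ 0.006 at r = 1).
Both `sem_mode="known"` and `"estimated"` are exposed, and the headline
stringency figure reported by the acceptance script is the normal-theory
(known-SEM) value, which is what a desk derivation of the criterion gives.

## Oscillation, pause, and synchrony detectors

These are operationalizations of judgements made by eye in practice; all
thresholds are arguments.

* **Oscillator flag** — events are local maxima of the analysis window
  (≥ 10 frames, by default everything before the first stimulus) exceeding
  `median + 3 × scaled MAD`, separated by ≥ 2 frames; a cell with ≥ 3
  events is an oscillator.  The MAD is computed one-sidedly from
  below-median deviations: the upward transients being detected would
  otherwise inflate the noise-scale estimate and suppress genuine events
  (for symmetric noise the one-sided estimate is consistent for the same
  SD).
* **Pause on peptide** — for pause assessment, events over the whole
  recording are extracted with a *prominence* criterion (3 × baseline MAD)
  rather than an absolute height, so transients riding on the slow
  peptide-induced dip still count.  The cell paused iff the first
  inter-event interval after application exceeds 2 × the median
  pre-application interval; the median is made robust to single missed
  events by folding intervals near integer multiples of the raw median.
  Events detected within 1.5 frames of the application time cannot be
  ordered against it at the frame rate and are counted with the
  pre-application train.  Cells with < 3 pre-application events (or no
  post-application event) are "not assessable".
* **Dual-ROI synchrony** — the lag of the cross-correlation maximum of the
  demeaned post-stimulus PHN and midpiece segments, positive when the PHN
  leads; |lag| ≤ 1 frame counts as simultaneous, and a peak normalized
  correlation below 0.5 triggers a low-confidence warning.

## The synthetic cohort generator

The generator emulates the study conditions so that the pipeline is
testable end to end.  The trace model is additive in percent space:

    F(t) = background + F0 · (1 + dF_true(t)/100) + ε(t),  ε ~ N(0, (σ/100)·F0)

with per-cell resting intensity `F0` ~ truncated normal (1000 ± 150 a.u.,
bounds 300–3000), background 100 a.u., and noise σ = 2% dF by default — so
the normalization stage can be verified against known `dF_true` exactly
when noise is off.  An optional linear drift term (default 0) exercises the
criterion's behaviour under drifting baselines.

Per-cell phenotypes are independent Bernoulli draws:

* **oscillator** p = 0.192; given oscillator, **pauses on peptide** with
  p = 0.428 (KIKKK) / 0.398 (scrambled) / 0.40 (control, not observed in
  the emulated design);
* **peptide dip responder** p = 0.65, with per-cell dip depth ~ truncated
  normal 10.2 ± 3.5% — 0.65 × 10.2% puts the population `R_tot` dip near
  6.6%; the dip is V-shaped, maximal 90 s after application, fully
  recovered by 180–240 s (uniform per cell);
* **progesterone responder** p = 0.985 / 0.961 / 0.959 (control /
  scrambled / KIKKK); among responders, the **prolonged** subtype is drawn
  so that its frequency among *all* cells is 0.088 / 0.063 / 0.152.

Response kinetics: a linear rise to the peak over 15–30 s (uniform), then
for conventional cells an exponential decay (τ uniform 20–40 s, so decay
to the plateau completes within 1–2 min) to a sustained plateau at a
per-cell fraction of the peak; prolonged cells hold the peak until 3–10 min
(uniform) after stimulation before the same decay.  Peak amplitudes are
truncated-normal 50 ± 15% dF.  Oscillations are spike trains (instant
rise, τ = 15 s decay) at a 100 s period with 3% timing jitter and 20% dF
amplitude; a pause stretches one inter-event interval to 2.5 periods.

**Calibration.**  The plateau-fraction means (0.225 control, 0.269
scrambled, 0.385 KIKKK; SD 0.12, bounds 0.02–0.65) are the one generator
quantity not taken directly from a reported number: they were set, once,
by a deterministic sweep so that the *pipeline-measured* cohort-mean S/T
ratio at the full study sizes reproduces the reported population means
(0.36 / 0.39 / 0.55).  Calibrating on the measured rather than the
nominal ratio matters because the 3-point peak mean of a sampled transient
underestimates the true peak by ~25%, inflating measured S/T by the same
factor — an effect equally present in real recordings analysed this way.

Seeding: all draws flow from one integer seed; cell *k* uses the
independent substream `default_rng([seed, k])`, so traces are bitwise
reproducible and unchanged when the cohort grows.

**What the generator does not emulate:** photophysics (bleaching, dye
saturation) beyond optional linear drift; correlated noise; cell–cell
heterogeneity in oscillation kinetics beyond amplitude/phase/jitter; any
dependence between phenotypes (oscillator status, dip response and
progesterone subtype are drawn independently — whether prolonged
responders overlap spontaneous oscillators is unknown, and this choice is
a candidate for sensitivity analysis).  Passing recovery tests on these
cohorts therefore demonstrates correctness of the pipeline's arithmetic
and robustness at realistic noise levels, not performance on every
pathology of real recordings.

## Population statistics

The experiment, not the cell, is the unit of replication: each arm summary
first computes per-experiment values (R_tot peak, early-sustained
amplitude, decay rate, responder proportion, prolonged fraction, mean S/T),
then reports their cross-experiment mean ± SEM.  Pairwise arm comparisons
use two-sided paired t-tests (paired by experiment set) on decay rate and
early-sustained amplitude, a paired t-test on arcsine-transformed
(`arcsin√p`) responder proportions, and Pearson's χ² (1 df, Yates
correction off by default, available as a flag) on pooled 2×2
prolonged-response tables; "k of n sets" sign counts are reported alongside
each paired test.  S/T histograms use fixed 0.05-wide bins over [0, 1.2],
with the fraction of ratios strictly above 0.9 reported separately.  No
multiple-testing correction is applied; p-values are raw.

## Numerical and design choices

* Frame lookup: nearest frame, half-frame ties toward the earlier frame;
  peak-argmax ties toward the earliest frame.
* Windows are closed intervals in seconds; at sampling rates other than
  0.1 Hz the 3-min window is the six frames ending two frames after the
  frame nearest stim+180 s.
* Degenerate inputs warn rather than fail where a convention exists:
  single-cell experiments (SEM ≡ 0), negative background-corrected
  intensities, zero-variance paired differences (p reported as 0).
* The default study layouts are a progesterone experiment with 200 s of
  baseline and 12 min of post-stimulus recording, and a peptide experiment
  with 400 s of baseline (enough to observe ≥3 oscillation events at the
  100 s default period) and 5 min after application.  Cohort sizes follow
  the emulated design: 9 experiments per arm totalling 424 / 474 / 408
  cells, 8 experiments of ~50 cells for the peptide dip, 18 for the
  oscillator fraction.
* Readers of delimited trace matrices validate rather than coerce:
  duplicate cell IDs, ragged rows, non-uniform time columns and missing
  values are rejected with context.

## Known limitations

* The prolonged-response proxy can miss a prolonged cell whose measured
  peak is inflated by a coincident oscillation spike (~10% of prolonged
  cells at default conditions); visual inspection would not be fooled the
  same way.
* Oscillator detection operates on the pre-stimulus window only; a
  progesterone-experiment baseline of 200 s is too short to flag a 100 s
  oscillator, so oscillator fractions should be estimated from the
  peptide-experiment layout (400 s baseline).
* The χ² test on reconstructed 2×2 counts is exact arithmetic on the
  counts given to it; building those counts from rounded percentages can
  shift p-values by orders of magnitude when they are small.
* `detect_pause` assesses only the first post-application interval; a cell
  that pauses twice, or pauses long after application, is out of scope.
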
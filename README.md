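# catrace

Analysis pipeline for **single-cell calcium fluorescence time series** of the
kind produced by slow time-lapse imaging (0.1 Hz) of dye-loaded cells — the
motivating system is human sperm loaded with Oregon Green BAPTA-1, where
progesterone triggers a biphasic intracellular-calcium response and
cell-penetrating peptides that mimic the basic patch of STIM1's SOAR/CAD
domain prolong the initial transient by interfering with store-operated
channel closure.

The package is aimed at people who have (or want to emulate) matrices of
per-cell fluorescence traces with stimulus annotations, and need the full
chain from raw intensities to comparative statistics:

* **Normalization** — background correction and percent change
  `dF = (F − F_rest)/F_rest × 100`, with `F_rest` the mean of ≥10 frames of
  the pre-stimulus control period; population trace `R_tot` (mean dF over
  all cells of an experiment) ± SEM.
* **Response metrics** — per cell: transient **peak amplitude** (mean of the
  three frames spanning the peak), **3-min amplitude** (six frames spanning
  2.5–3.5 min post-stimulus), **decay rate** (least-squares slope over
  1.5–2 min, %/min), and the **S/T ratio** (mean sustained signal 3–5 min
  post-stimulus ÷ transient peak — ≈1 marks a prolonged, monophasic
  response).
* **Response detection** — the **CI-sum criterion**: a response is
  significant when |peak mean − pre mean| exceeds the sum of the two
  samples' 95% confidence intervals (10 pre-stimulus frames vs 3 peak
  frames, CI = 1.96 × SEM).
* **Alpha characterization** — closed form and Monte-Carlo type-I error of
  that criterion as a function of the SEM ratio r of the two samples:
  `alpha(r) = 2(1 − Φ(1.96(1+r)/√(1+r²)))`, i.e. 0.05 when one sample is
  noiseless, 0.0056 at equal SEMs — plus the markedly less stringent
  behaviour when the SEMs are estimated from the samples.
* **Detectors** — spontaneous-oscillation events (median + 3×MAD local
  maxima), peptide-induced pause/reset of oscillations, prolonged-response
  classification (3-min amplitude ≥ 0.9 × peak), dual-ROI synchrony lag.
* **Population statistics** — per-experiment summaries (the experiment is
  the unit of replication), paired t-tests across parallel experiment sets,
  arcsine-transformed responder proportions, Pearson χ² on 2×2
  prolonged-response tables, S/T histograms.
* **Synthetic cohorts** — a seedable generator that emulates the study
  conditions (spontaneous oscillators, peptide dips, conventional /
  prolonged progesterone responses at arm-specific frequencies) and emits
  ground-truth labels, so every stage of the pipeline is testable without
  any recordings.

## Worked example

```python
import numpy as np
import catrace as ct

params = ct.PhenotypeParams()                      # study-condition defaults
tb     = ct.progesterone_experiment_timebase()     # 0.1 Hz, stimulus at 200 s
design = ct.ExperimentDesign(arm="KIKKK", n_cells=60,
                             experiment_id="demo", progesterone_time_s=200.0)

traces, truth = ct.generate_cohort(design, params, tb, seed=2)
metrics = ct.compute_cell_metrics(ct.normalize(traces))
st = metrics["st_ratio"].to_numpy(float)
print(f"responders: {metrics['responder'].mean():.1%}   "
      f"prolonged: {metrics['prolonged'].mean():.1%}   "
      f"mean S/T: {np.nanmean(st):.2f}")
```

prints

```
responders: 96.7%   prolonged: 18.3%   mean S/T: 0.56
```

— almost every cell responds to progesterone, about one cell in six holds
its transient as a plateau for ≥3 min (the KIKKK-enriched phenotype), and
the cohort-mean S/T ratio sits near 0.55, well above the ~0.36 of a
control-arm cohort.  The `examples/` directory has one short script per
capability (simulation + normalization, per-cell metrics, alpha
characterization, full three-arm study with its JSON report), and the
`catrace` CLI exposes the same stages as `simulate`, `normalize`,
`metrics`, `summarize` and `alpha-sim` subcommands.

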
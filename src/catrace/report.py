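"""End-to-end study orchestration and machine-readable run reports.

A "study" is the full comparative design: three treatment arms (control,
scrambled peptide, KIKKK peptide) run as N parallel experiment sets.  The
report collects per-arm summaries, the pairwise comparative tests (paired
t-tests on decay rate and early-sustained amplitude, paired t-test on
arcsine-transformed responder proportions, chi-square on prolonged
fractions, with per-set sign counts alongside each paired test), an alpha
characterization of the detection criterion, and a config echo sufficient
to reproduce the run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import AlphaSimConfig, simulate_alpha
from .io import ARMS, ExperimentDesign
from .metrics import compute_cell_metrics
from .normalize import NormalizedTraceSet, normalize
from .stats import (
    ArmSummary,
    ContingencyTable2x2,
    arcsine_transform,
    chi_square_2x2,
    paired_ttest,
    summarize_arm,
)
from .synth import (
    PhenotypeParams,
    generate_cohort,
    progesterone_experiment_timebase,
    split_cells,
)

__all__ = ["run_arm", "run_study", "build_report", "write_report", "read_report"]

SCHEMA_VERSION = 1

#: default arm cohort sizes (total cells over 9 parallel experiments)
DEFAULT_ARM_TOTALS = {"control": 424, "scrambled": 474, "KIKKK": 408}


def experiment_seed(seed: int, arm: str, exp_index: int) -> int:
    """Deterministic per-experiment child seed (stable across runs)."""
    return (int(seed) * 100_003 + ARMS.index(arm) * 1_009 + exp_index) % (2**31)


def run_arm(
    arm: str,
    params: PhenotypeParams,
    seed: int,
    n_experiments: int = 9,
    total_cells: int | None = None,
    timebase=None,
) -> tuple[list[NormalizedTraceSet], list[pd.DataFrame], list[pd.DataFrame]]:
    """Generate, normalize and measure one arm's experiments.

    Returns ``(normalized_sets, metrics_tables, ground_truths)``, one entry
    per experiment.
    """
    if total_cells is None:
        total_cells = DEFAULT_ARM_TOTALS[arm]
    if timebase is None:
        timebase = progesterone_experiment_timebase()
    stim = timebase.event_time("progesterone")
    norms, mets, gts = [], [], []
    for j, n_cells in enumerate(split_cells(total_cells, n_experiments)):
        design = ExperimentDesign(
            arm=arm,
            n_cells=n_cells,
            experiment_id=f"{arm}_e{j}",
            set_id=f"set{j}",
            progesterone_time_s=stim,
        )
        ts, gt = generate_cohort(design, params, timebase, experiment_seed(seed, arm, j))
        norm = normalize(ts)
        norms.append(norm)
        mets.append(compute_cell_metrics(norm))
        gts.append(gt)
    return norms, mets, gts


def run_study(
    params: PhenotypeParams | None = None,
    seed: int = 0,
    n_experiments: int = 9,
    arm_totals: dict | None = None,
    timebase=None,
) -> dict:
    """Run all three arms; returns ``{arm: (norms, metrics, ground_truths)}``."""
    params = params or PhenotypeParams()
    arm_totals = arm_totals or DEFAULT_ARM_TOTALS
    return {
        arm: run_arm(arm, params, seed, n_experiments, arm_totals[arm], timebase)
        for arm in ARMS
    }


def _sign_count(x: np.ndarray, y: np.ndarray) -> str:
    """'k of n' sets in which x > y (the per-set sign pattern)."""
    return f"{int(np.sum(np.asarray(x) > np.asarray(y)))} of {len(x)}"


def pairwise_tests(summaries: dict[str, ArmSummary], alpha_level: float = 0.05) -> list[dict]:
    """All pairwise arm comparisons the study design calls for.

    For each arm pair: paired t on decay rate, on early-sustained R_tot
    amplitude and on arcsine-transformed responder proportions (paired by
    experiment set), and chi-square on pooled prolonged counts.
    """
    tests: list[dict] = []
    for a, b in combinations(summaries, 2):
        pa, pb = summaries[a].per_experiment, summaries[b].per_experiment
        n = min(len(pa), len(pb))
        paired_specs = [
            ("decay_rate", "rtot_decay_rate_pct_per_min", lambda v: v),
            ("early_sustained_amplitude", "rtot_early_sustained_pct", lambda v: v),
            ("responder_proportion_arcsine", "responder_proportion", arcsine_transform),
        ]
        for name, col, f in paired_specs:
            x = f(pa[col].to_numpy(float)[:n])
            y = f(pb[col].to_numpy(float)[:n])
            t, p, df = paired_ttest(x, y)
            tests.append(
                {
                    "comparison": f"{a} vs {b}",
                    "quantity": name,
                    "test": "paired t-test",
                    "statistic": t,
                    "p": p,
                    "n": n,
                    "sign": _sign_count(x, y),
                    "significant": bool(p < alpha_level),
                }
            )
        # pooled prolonged counts across each arm's experiments
        counts = {}
        for arm in (a, b):
            pe = summaries[arm].per_experiment
            n_prol = int(round((pe["prolonged_fraction"] * pe["n_cells"]).sum()))
            counts[arm] = (n_prol, int(pe["n_cells"].sum()) - n_prol)
        table = ContingencyTable2x2(*counts[a], *counts[b])
        chi2, p = chi_square_2x2(table)
        tests.append(
            {
                "comparison": f"{a} vs {b}",
                "quantity": "prolonged_fraction",
                "test": "chi-square (2x2, Pearson)",
                "statistic": chi2,
                "p": p,
                "n": int(table.as_array().sum()),
                "table": [counts[a], counts[b]],
                "significant": bool(p < alpha_level),
            }
        )
    return tests


def _arm_summary_dict(s: ArmSummary) -> dict:
    return {
        "arm": s.arm,
        "n_cells": s.n_cells,
        "mean": s.mean,
        "sem": s.sem,
        "per_experiment": s.per_experiment.to_dict(orient="records"),
        "st_hist_counts": None if s.st_hist_counts is None else s.st_hist_counts.tolist(),
        "st_hist_edges": None if s.st_hist_edges is None else np.round(s.st_hist_edges, 10).tolist(),
        "fraction_st_gt_0_9": s.fraction_st_gt_0_9,
    }


def build_report(
    summaries: dict[str, ArmSummary],
    tests: list[dict] | None = None,
    config: dict | None = None,
    alpha_cfg: AlphaSimConfig | None = None,
) -> dict:
    """Assemble the run report (JSON-serializable dict).

    Requires all three arms.  Every p-value entry is tagged with the test
    name and the n it used; the config echo (parameters + seeds + version)
    suffices to reproduce the run.
    """
    missing = [a for a in ARMS if a not in summaries]
    if missing:
        raise ValueError(f"missing arm(s) in report: {missing}")
    if tests is None:
        tests = pairwise_tests(summaries)
    alpha_section = None
    if alpha_cfg is not None:
        res = simulate_alpha(alpha_cfg)
        alpha_section = {
            "alpha_hat": res.alpha_hat,
            "mc_se": res.mc_se,
            "alpha_analytic": res.alpha_analytic,
            "config": asdict(res.config),
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "arms": {a: _arm_summary_dict(summaries[a]) for a in ARMS},
        "pairwise_tests": tests,
        "alpha_sim": alpha_section,
        "config_echo": config or {},
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def run_and_report(
    params: PhenotypeParams | None = None,
    seed: int = 0,
    n_experiments: int = 9,
    arm_totals: dict | None = None,
    alpha_trials: int = 20_000,
) -> dict:
    """Convenience wrapper: full study -> summaries -> tests -> report."""
    params = params or PhenotypeParams()
    study = run_study(params, seed, n_experiments, arm_totals)
    summaries = {arm: summarize_arm(norms, mets) for arm, (norms, mets, _) in study.items()}
    cfg = AlphaSimConfig(n_trials=alpha_trials, seed=seed, sem_ratio=1.0)
    config_echo = {
        "seed": int(seed),
        "n_experiments": n_experiments,
        "arm_totals": arm_totals or DEFAULT_ARM_TOTALS,
        "params": params.to_dict(),
    }
    return build_report(summaries, config=config_echo, alpha_cfg=cfg)
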
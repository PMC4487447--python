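import numpy as np
import pytest

import catrace as ct


@pytest.fixture(scope="session")
def default_params():
    return ct.PhenotypeParams()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, phenotype-free parameters: pure constant baselines."""
    return ct.PhenotypeParams(
        p_oscillator=0.0,
        p_peptide_responder=0.0,
        p_progesterone_responder={"control": 0.0, "scrambled": 0.0, "KIKKK": 0.0},
        p_prolonged={"control": 0.0, "scrambled": 0.0, "KIKKK": 0.0},
        noise_sd_pct=0.0,
        baseline_intensity_sd=0.0,
    )


@pytest.fixture(scope="session")
def prog_tb():
    return ct.progesterone_experiment_timebase()  # stim at 200 s, 93 frames


@pytest.fixture(scope="session")
def pep_tb():
    return ct.peptide_experiment_timebase()  # application at 400 s, 71 frames


@pytest.fixture(scope="session")
def control_cohort(default_params, prog_tb):
    """One seeded control-arm experiment at default study conditions."""
    design = ct.ExperimentDesign(
        arm="control", n_cells=120, experiment_id="ctl", progesterone_time_s=200.0
    )
    ts, gt = ct.generate_cohort(design, default_params, prog_tb, seed=42)
    norm = ct.normalize(ts)
    return ts, gt, norm
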
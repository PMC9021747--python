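import numpy as np
import pandas as pd
import pytest

from injuryarch import synthetic_cohort
from injuryarch.synthetic_cohort import SimulationConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Shared synthetic cohort: 250 biopsies, fixed seed."""
    cfg = SimulationConfig(n_biopsies=250, seed=11)
    scores, clinical, expr, truth = synthetic_cohort.simulate_cohort(cfg)
    return {
        "config": cfg,
        "scores": scores,
        "clinical": clinical,
        "expr": expr,
        "truth": truth,
    }


@pytest.fixture()
def toy_clinical():
    """Five hand-written biopsies covering the clinical schema."""
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4", "S5"],
            "patient_id": ["P1", "P1", "P2", "P3", "P4"],
            "days_post_transplant": [30, 400, 42, 43, 2000],
            "egfr": [22.0, 55.0, 30.0, np.nan, 31.0],
            "proteinuria_positive": [True, False, None, True, False],
            "donor_age": [61.0, 35.0, 50.0, 52.0, np.nan],
            "deceased_donor": [True, False, True, None, True],
            "dgf": [True, False, False, False, None],
            "ci_score": [2, 0, 1, 3, None],
            "ct_score": [1, 0, 2, 3, 1],
            "i_score": [0, 0, 1, 2, 0],
            "ti_score": [0, 1, 1, 2, 0],
            "histology_dx": [
                "no major abnormalities", "IFTA", "no major abnormalities",
                "ABMR", "other",
            ],
            "rejection_group": ["no-rejection", "EABMR", "no-rejection", "FABMR", "TCMR"],
            "pct_cortex_estimate": [80.0, 5.0, 50.0, np.nan, 95.0],
            "followup_days": [1200, 340, 1100, 900, 80],
            "graft_failed": [False, True, False, False, False],
            "died_with_function": [False, False, False, False, True],
        }
    )
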
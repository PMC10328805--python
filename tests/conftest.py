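import numpy as np
import pandas as pd
import pytest

from glycopipe.synthetic import EhrConfig, SimTruth, generate_ehr

DRUG_EFFECTS = {
    "EXP_A": (-0.5, -10.0),
    "DEC_B": (-1.0, -30.0),
    "INC_C": (0.3, 5.0),
}
DRUG_GROUPS = {
    "EXP_A": "experimental",
    "DEC_B": "glucose_decreasing",
    "INC_C": "glucose_increasing",
}


def make_truth(seed: int = 0) -> SimTruth:
    return SimTruth(
        drug_effects=dict(DRUG_EFFECTS), drug_groups=dict(DRUG_GROUPS), seed=seed
    )


def noiseless_config(n_patients: int = 200, seed: int = 5, dialect: str = "fills") -> EhrConfig:
    """Generator settings that switch off every stochastic nuisance."""
    return EhrConfig(
        n_patients=n_patients,
        noise_sd={"hba1c": 0.0, "glucose": 0.0},
        contamination_fraction=0.0,
        pregnancy_rate=0.0,
        missing_baseline_fraction=0.0,
        inpatient_fraction=0.0,
        qc_outlier_fraction=0.0,
        persistent_fraction=1.0,
        dialect=dialect,
        seed=seed,
    )


@pytest.fixture(scope="session")
def truth():
    return make_truth()


@pytest.fixture(scope="session")
def ehr_tables(truth):
    cfg = EhrConfig(n_patients=600, dialect="fills", seed=11)
    return generate_ehr(cfg, truth)


@pytest.fixture(scope="session")
def noiseless_tables(truth):
    return generate_ehr(noiseless_config(), truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
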
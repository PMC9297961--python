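import numpy as np
import pandas as pd
import pytest

from epiclock import BetaMatrix, SampleTable, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A light synthetic cohort shared by read-only tests."""
    cfg = SimConfig(seed=5, n_animals=40, repeat_fraction=0.1, n_cpgs=300,
                    n_age_cpgs=30, n_sex_basal_cpgs=15, n_interaction_cpgs=10)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture()
def tiny_beta():
    """Hand-sized 4-sample x 3-CpG matrix."""
    return BetaMatrix(pd.DataFrame(
        [[0.10, 0.50, 0.90],
         [0.20, 0.60, 0.80],
         [0.30, 0.40, 0.70],
         [0.40, 0.30, 0.60]],
        index=["S1", "S2", "S3", "S4"], columns=["cg1", "cg2", "cg3"]))


@pytest.fixture()
def tiny_samples():
    return SampleTable(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "animal_id": ["A1", "A2", "A3", "A3"],
        "age_years": [0.67, 2.0, 8.0, 9.0],
        "sex": ["female", "male", "female", "male"],
        "population": ["TF", "CH", "TF", "CH"],
        "body_mass_kg": [14.0, 22.0, 26.0, 27.5],
    }))


def rng_beta_frame(rng, n_samples, n_cpgs):
    vals = rng.uniform(0.05, 0.95, size=(n_samples, n_cpgs))
    return pd.DataFrame(vals,
                        index=[f"S{i+1}" for i in range(n_samples)],
                        columns=[f"cg{j+1}" for j in range(n_cpgs)])
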
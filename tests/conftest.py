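import numpy as np
import pandas as pd
import pytest

import hmcseal as h
from hmcseal.features import CountMatrix


@pytest.fixture(scope="session")
def small_catalog():
    return h.generate_catalog(2, 50, ["H3K4me1"], seed=7)


@pytest.fixture(scope="session")
def small_effects(small_catalog):
    return h.simulate_effects(small_catalog, n_disease_genes=20, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_effects):
    cfg = h.SimulationConfig(n_cancer=8, n_control=10, seed=13)
    return h.simulate_cohort(small_effects, cfg)


def make_two_group_counts(
    n_per_group: int,
    n_features: int,
    mu_control: float,
    fold: float,
    dispersion: float,
    seed: int,
    lib_spread: float = 0.0,
) -> CountMatrix:
    """NB counts for a plain two-group comparison (constant covariates)."""
    rng = np.random.default_rng(seed)
    libs = np.exp(rng.normal(0.0, lib_spread, size=2 * n_per_group))
    mu = np.where(np.arange(2 * n_per_group) < n_per_group, mu_control * fold, mu_control)
    mean = np.outer(np.ones(n_features), mu * libs)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    samples = [f"s{i:03d}" for i in range(2 * n_per_group)]
    df = pd.DataFrame(counts, index=[f"g{j:04d}" for j in range(n_features)], columns=samples)
    meta = pd.DataFrame(
        {
            "status": ["cancer"] * n_per_group + ["healthy"] * n_per_group,
            "cancer_type": "colorectal",
            "stage": "NA",
            "age_group": "20-55",
            "technician": "tech1",
            "batch": "b1",
            "patient_id": samples,
            "tumor_fraction": 0.0,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(df, meta)
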
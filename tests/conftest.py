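import numpy as np
import pandas as pd
import pytest

import netdist as nd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_covariates():
    """Six subjects with mixed continuous / categorical covariates."""
    return pd.DataFrame(
        {
            "AGE": [10, 12, 15, 11, 14, 13],
            "SEX": ["F", "F", "M", "M", "F", "M"],
            "TRT": ["treatment", "placebo", "treatment", "placebo", "placebo", "treatment"],
            "IQ": [95, 110, 102, 98, 120, 105],
        },
        index=pd.Index([f"S{k}" for k in range(1, 7)], name="subject_id"),
    )


@pytest.fixture
def toy_table(toy_covariates):
    return nd.CovariateTable(
        toy_covariates, continuous=("AGE", "IQ"), categorical=("SEX", "TRT"), coi="IQ"
    )


def simulated_regression(n_p=20, seed=0, signal=0.0, metric="euclidean"):
    """Small simulated y/X instance on the pair graph (shared by many tests)."""
    cov = nd.simulate_covariates(n_p, seed)
    D = nd.simulate_degree_matrix(nd.layout(1, n_n=60), cov, signal, seed + 1)
    table = nd.CovariateTable(
        cov, continuous=("AGE", "IQ"), categorical=("SEX", "TRT"), coi="IQ"
    )
    y, _, _ = nd.condensed_values(D, metric)
    return y, table
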
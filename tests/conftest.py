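import numpy as np
import pandas as pd
import pytest

import ectosize as es
from ectosize.pipeline import COLUMN_TO_PREDICTOR
from ectosize.simulate import MODEL_COVARIATES


@pytest.fixture(scope="session")
def darwinii_spec():
    return es.darwinii_like_scenario(seed=42)


@pytest.fixture(scope="session")
def darwinii_tables(darwinii_spec):
    return es.simulate_tables(darwinii_spec)


@pytest.fixture(scope="session")
def darwinii_summaries(darwinii_tables, darwinii_spec):
    sites, individuals = darwinii_tables
    fit = es.fit_sma(individuals, include_juveniles=True)
    params = es.SMIParams(b_sma=fit.b_sma, l0=darwinii_spec.smi_l0)
    return es.site_summaries(individuals, params, sites=sites)


@pytest.fixture(scope="session")
def darwinii_design(darwinii_tables):
    sites, _ = darwinii_tables
    return sites[list(MODEL_COVARIATES)].rename(columns=COLUMN_TO_PREDICTOR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
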
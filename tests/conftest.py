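"""Shared fixtures: small synthetic datasets and pre-fitted models.

Everything is generated at test time from fixed seeds; the heavier
fitted-model fixtures are session-scoped so each model is fitted once.
"""

import numpy as np
import pandas as pd
import pytest

from fleetbycatch import glmm, synthetic


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimConfig:
    return synthetic.SimConfig(
        n_vessels=20,
        years=(2018, 2019, 2020),
        n_days_per_vessel_year=12,
        em_fraction=1.0,
        seed=501,
    )


@pytest.fixture(scope="session")
def true_params() -> synthetic.TrueParams:
    beta = dict(synthetic.TrueParams().beta, intercept=-3.9)
    return synthetic.TrueParams(beta=beta)


@pytest.fixture(scope="session")
def small_dataset(small_config, true_params):
    """(fleet effort, EM table) — EM is a census here (em_fraction 1)."""
    return synthetic.simulate_dataset(small_config, true_params)


@pytest.fixture(scope="session")
def em_table(small_dataset) -> pd.DataFrame:
    return small_dataset[1]


@pytest.fixture(scope="session")
def fitted_plain(em_table) -> glmm.FittedModel:
    """No random effects: fixed-effects NB2 fit."""
    spec = glmm.ModelSpec(random_terms=(), spatial_grouping="none")
    return glmm.fit(em_table, spec)


@pytest.fixture(scope="session")
def fitted_year(em_table) -> glmm.FittedModel:
    """Year random intercept, no spatial field."""
    spec = glmm.ModelSpec(random_terms=("year",), spatial_grouping="none")
    return glmm.fit(em_table, spec, glmm.FitOptions(compute_param_cov=True))


@pytest.fixture(scope="session")
def fitted_spatial(em_table) -> glmm.FittedModel:
    """Year intercept plus quarter-within-year spatial fields."""
    spec = glmm.ModelSpec(
        random_terms=("year",), spatial_grouping="quarter_within_year"
    )
    return glmm.fit(em_table, spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
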
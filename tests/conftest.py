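import numpy as np
import pandas as pd
import pytest

from mrcea.mr import RegressionSpec
from mrcea.synth import GeneratorConfig, generate_cohort

#: light regression spec used by simulation studies (no centre/PC one-hots)
LIGHT_SPEC = RegressionSpec(outcome="qalys_per_year", covariates=("age", "sex"), categorical=())


@pytest.fixture(scope="session")
def annual_cohort():
    """Medium synthetic cohort on the annual outcome channel."""
    return generate_cohort(GeneratorConfig(n_individuals=8000, seed=11), channel="annual")


@pytest.fixture(scope="session")
def annual_data(annual_cohort):
    return annual_cohort.analysis_table()


@pytest.fixture()
def toy_iv_table():
    """Fixed 8-row table for exact linear-algebra oracles."""
    return pd.DataFrame(
        {
            "y": [1.0, 2.0, 1.5, 3.0, 2.5, 4.0, 3.5, 5.0],
            "bmi": [22.0, 25.0, 24.0, 28.0, 27.0, 31.0, 30.0, 34.0],
            "prs": [-0.5, 0.2, 0.0, 0.9, 0.6, 1.4, 1.1, 2.0],
            "age": [45.0, 50.0, 47.0, 55.0, 52.0, 60.0, 58.0, 65.0],
        }
    )


@pytest.fixture()
def toy_spec():
    return RegressionSpec(outcome="y", covariates=("age",), categorical=())


def light_spec(outcome: str) -> RegressionSpec:
    return RegressionSpec(outcome=outcome, covariates=("age", "sex"), categorical=())
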
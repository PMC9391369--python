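import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (88 patients, 3 sites, planted effects)."""
    from protsurv.synthetic import GeneratorParams, generate_cohort

    return generate_cohort(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def patient_data(cohort):
    """Patient-level prediction matrix + labels + site covariates."""
    from protsurv.proteomics import (channel_sum_normalize, filter_proteins,
                                     average_replicates)

    normalized = channel_sum_normalize(cohort.expression)
    pred, _ = filter_proteins(normalized)
    patients = average_replicates(pred)
    clin = cohort.clinical.df.loc[list(patients.values.columns)]
    return {
        "matrix": patients,
        "labels": clin["survived"].to_numpy(dtype=int),
        "sites": clin["site"],
        "site_covariates": pd.get_dummies(
            clin["site"], drop_first=True).to_numpy(dtype=float),
        "clinical": clin,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
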
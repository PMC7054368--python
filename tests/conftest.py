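import numpy as np
import pytest

import twincycle as tc
from twincycle.pipeline import RunConfig, preprocess_cohort


@pytest.fixture(scope="session")
def tcpa_model():
    return tc.builtin_model("TC-PA")


@pytest.fixture(scope="session")
def tc_model():
    return tc.builtin_model("TC")


@pytest.fixture(scope="session")
def cohort1_spec():
    """Synthetic prediabetes cohort at the study's TC-PA sample size."""
    return tc.SyntheticCohortSpec(cohort=1, model_name="TC-PA", n=725, seed=20260929)


@pytest.fixture(scope="session")
def cohort1_fit(cohort1_spec, tcpa_model):
    """Full-pipeline fit of the TC-PA model on one synthetic cohort."""
    cohort = tc.generate_cohort(cohort1_spec)
    config = RunConfig(synthetic=cohort1_spec, output_dir="scratch/conftest")
    analysis = preprocess_cohort(cohort, tcpa_model.nodes, config)
    data = tc.covariance_input(analysis, tcpa_model.nodes)
    return tc.fit_model(tcpa_model, data, compute_se=True, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
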
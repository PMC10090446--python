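import numpy as np
import pytest

from pmxnpag import (CohortDesign, CovariateModel, ErrorSpec, PKParameters,
                     generate_cohort)


@pytest.fixture(scope="session")
def table_params():
    """Reported two-compartment population means."""
    return PKParameters(CL=1.24, Vc=16.64, Q=3.04, Vp=66.2)


@pytest.fixture(scope="session")
def sparse_cohort():
    """Default 22-subject sparse-sampling cohort (64 observations)."""
    cohort, truth = generate_cohort(CohortDesign(), seed=20220901)
    return cohort, truth


@pytest.fixture(scope="session")
def rich_cohort_small():
    """Small rich-sampling cohort without covariate effects, for estimator
    unit tests that need identifiable data but not the full study size."""
    design = CohortDesign(n_subjects=12, sampling_mode="rich",
                          truth_covariates=CovariateModel())
    cohort, truth = generate_cohort(design, seed=2024)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
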
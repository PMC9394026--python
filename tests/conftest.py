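import pytest

from objscd.neuropsych import fit_normative_model
from objscd.synthetic import CohortConfig, generate_cohort, generate_reference_sample


@pytest.fixture(scope="session")
def config():
    return CohortConfig(seed=7)


@pytest.fixture(scope="session")
def reference_sample(config):
    return generate_reference_sample(config, n_ref=800)


@pytest.fixture(scope="session")
def norms(reference_sample):
    return fit_normative_model(reference_sample)


@pytest.fixture(scope="session")
def cohort(config, norms):
    df, log = generate_cohort(config, norms)
    return df
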
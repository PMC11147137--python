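import numpy as np
import pytest
from hypothesis import settings

from vitdmet.preprocess import impute_halfmin, log_zscore, qc_filter
from vitdmet.simulate import SimConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-mother, 60-metabolite cohort with a planted 8-metabolite signal."""
    cfg = SimConfig(n_mothers=80, n_metabolites=60, n_subpathways=6,
                    n_signal_metabolites=8, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_zscored(small_cohort):
    return log_zscore(impute_halfmin(qc_filter(small_cohort.metabolome)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
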
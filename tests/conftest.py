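import numpy as np
import pandas as pd
import pytest

from symptomnet.ggm import EstimatorConfig
from symptomnet.simulate import GeneratorConfig, default_truth, generate_cohort, sample_items


@pytest.fixture(scope="session")
def sdg_truth():
    return default_truth("SDG", include_parental=False)


@pytest.fixture(scope="session")
def nsdg_truth():
    return default_truth("NSDG", include_parental=False)


@pytest.fixture(scope="session")
def sdg_items_3000(sdg_truth):
    """Ordinal items from the SDG truth, n=3000 (shared across tests)."""
    cfg = GeneratorConfig(n_per_group=3000, seed=11)
    return sample_items(sdg_truth, cfg, "SDG", n=3000)


@pytest.fixture(scope="session")
def small_cohort():
    """Full generated cohort, modest size, default conditions."""
    return generate_cohort(GeneratorConfig(n_per_group=1000, seed=5))


@pytest.fixture(scope="session")
def fast_estimator():
    """Coarser penalty grid for resampling-heavy tests."""
    return EstimatorConfig(nlambda=10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
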
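import numpy as np
import pytest

from dcoex import CohortConfig, generate_cohort
from dcoex.fixtures import demo_network_inputs


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort (5/group, 84 genes, planted modules + DE)."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """No missing values or outliers; used where corruption is a nuisance."""
    return generate_cohort(
        CohortConfig(seed=43, missing_rate=0.0, outlier_rate=0.0)
    )


@pytest.fixture(scope="session")
def network_demo():
    expr, groups, curated = demo_network_inputs()
    return expr, groups, curated


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
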
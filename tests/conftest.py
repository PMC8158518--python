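import numpy as np
import pytest

import liponet as lp


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design synthetic cohort, shared across tests."""
    return lp.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_groups(default_cohort):
    return lp.stratify_by_age(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for the slower integration paths."""
    spec = lp.SyntheticCohortSpec(
        group_sizes={"M": 120, "W": 90},
        strata_sizes={"YM": 40, "OM": 40, "YW": 30, "OW": 30},
    )
    return lp.generate_cohort(spec, seed=11)
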
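import numpy as np
import pandas as pd
import pytest

from shockbias.config import MasterConfig, default_marginals


@pytest.fixture
def marginals():
    return default_marginals()


@pytest.fixture
def master():
    return MasterConfig(seed=1)


@pytest.fixture
def small_master():
    return MasterConfig(seed=1, n=500)


@pytest.fixture
def equal_cohort(master):
    from shockbias.cohort import simulate_cohort

    return simulate_cohort(master.scenario("equal"))


def make_tables(transfusion, singleton_classes, composite_classes):
    """Hand-built row-aligned cohort/class tables for statistics tests."""
    n = len(transfusion)
    cohort = pd.DataFrame(
        {
            "hr": np.full(n, 80.0),
            "sbp": np.full(n, 125.0),
            "gcs": np.full(n, 15),
            "bd": np.full(n, 1.0),
            "transfusion": np.asarray(transfusion, dtype=float),
        }
    )
    classes = pd.DataFrame(
        {
            "hr_class": np.asarray(singleton_classes, dtype=int),
            "sbp_class": np.ones(n, dtype=int),
            "gcs_class": np.ones(n, dtype=int),
            "bd_class": np.asarray(singleton_classes, dtype=int),
            "composite_class": np.asarray(composite_classes, dtype=int),
        }
    )
    return cohort, classes
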
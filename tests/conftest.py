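import numpy as np
import pandas as pd
import pytest

from methylcog import CohortConfig, generate_cohort, generate_test_battery


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_subjects=400, n_probes=120, n_causal=12, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One modest cohort shared (read-only) across test modules."""
    pheno, beta, truth = generate_cohort(small_config)
    battery = generate_test_battery(truth.g_true, small_config)
    return {"config": small_config, "pheno": pheno, "beta": beta,
            "truth": truth, "battery": battery}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
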
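import warnings

import numpy as np
import pytest

import conncca as cc


@pytest.fixture(scope="session")
def planted_result():
    """One full desk-scale pipeline run on the planted single-mode cohort
    (300 subjects, 50 nodes, 500 permutations), shared across tests."""
    config = cc.PipelineConfig(
        spec=cc.CohortSpec(seed=7),
        d=30,
        n_perm=500,
        cv_reps=10,
        cv_perms=99,
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cc.run_pipeline(config)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort for unit-level checks (fast to generate)."""
    spec = cc.CohortSpec(
        n_mz_families=5, n_dz_families=5, n_sib_families=5, n_singles=20,
        n_nodes=20, n_timepoints=200, n_sms=15, seed=3,
    )
    return cc.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
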
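import numpy as np
import pandas as pd
import pytest

import cfjoint as cj


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic registry of 60 patients at the default study conditions."""
    raw = cj.simulate_cohort(cj.CohortConfig(n_patients=60, seed=11))
    return raw


@pytest.fixture(scope="session")
def small_registry(small_cohort):
    return small_cohort.to_registry()


@pytest.fixture(scope="session")
def small_joint_draws(small_registry):
    """A short joint fit shared by post-processing tests."""
    cfg = cj.MCMCConfig(n_chains=2, n_iterations=700, n_burnin=300, seed=5)
    return cj.run_mcmc(small_registry, "joint-semiparametric", config=cfg)


def toy_long_frame(rows):
    """Build a longitudinal table from (patient_id, age, fev1) triples with
    benign covariates."""
    df = pd.DataFrame(rows, columns=["patient_id", "age", "fev1"])
    df["male"] = 0
    df["birth_cohort"] = "gt1994"
    df["low_ses"] = 0
    for c in ("cfrd", "mrsa", "b_cepacia", "pa"):
        df[c] = 0
    return df


def toy_event_frame(entries):
    """Build an event table from (patient_id, time, status) triples."""
    return pd.DataFrame(entries, columns=["patient_id", "time", "status"])


@pytest.fixture
def toy_registry():
    """Two patients, hand-constructed."""
    long = toy_long_frame(
        [(1, 6.0, 95.0), (1, 7.0, 93.0), (1, 8.5, 92.0), (2, 10.0, 80.0), (2, 11.0, 78.0)]
    )
    events = toy_event_frame([(1, 3.0, 0), (2, 1.5, 1)])
    return cj.Registry(long=long, events=events)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
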
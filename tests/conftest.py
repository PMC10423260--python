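"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from oxidiag.experiments import detectability_conditions
from oxidiag.preprocess import preprocess_cohort, sim_to_raw
from oxidiag.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def detect_cohort():
    """50 records under the standard detectability conditions (depths >= 4%,
    sensor noise sd 0.3%), with exact ground truth."""
    records, manifest = simulate_cohort(detectability_conditions(seed=202))
    return records, manifest


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-conditions cohort, preprocessed."""
    cfg = SimConfig(seed=77, n_records=30, record_hours=(4.5, 6.5))
    records, manifest = simulate_cohort(cfg)
    cleans, log = preprocess_cohort([sim_to_raw(r) for r in records],
                                    [r.true_ahi for r in records])
    return records, cleans, log


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
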
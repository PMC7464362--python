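"""Shared fixtures: small synthetic cohorts and one expensive growth-model
fit reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from milemet import (GrowthCurveModel, SimulationConfig, eligibility_filter,
                     simulate_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions: 300 subjects, 12 visits, noise 0.3."""
    return simulate_cohort(seed=20260927)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for structural tests (50 subjects)."""
    cfg = SimulationConfig(n_per_sex=25, module_sizes=(25, 25),
                           n_background_metabolites=20, n_reference=4000)
    return simulate_cohort(cfg, seed=5)


@pytest.fixture(scope="session")
def fitted_growth(default_cohort):
    """Mixed-model fit on the default cohort (shared: it is expensive)."""
    records = eligibility_filter(default_cohort.anthropometry)
    return GrowthCurveModel().fit(records)


@pytest.fixture(scope="session")
def milestone_recovery(default_cohort, fitted_growth):
    """Per-subject milestone estimates joined against ground truth."""
    est = fitted_growth.extract_all_milestones()
    truth = default_cohort.ground_truth.milestones
    return est.merge(truth, on="subject_id", suffixes=("_hat", "_true"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
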
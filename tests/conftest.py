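"""Shared fixtures: small simulated cohorts sized for fast tests."""

import warnings

import pytest

from hrvscrub.model import SleepScrubReliability
from hrvscrub.synthetic import SimulationConfig, simulate_sessions


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # tiny fixtures routinely trigger the collinearity clip warning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*clipped before Fisher.*")
        yield


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort (8 subjects, 120 volumes, 16 ROIs) for pipeline tests."""
    return SimulationConfig(n_subjects=8, n_volumes=120, n_rois=16, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_sessions(small_config)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return SleepScrubReliability(small_cohort, n_random_draws=60)
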
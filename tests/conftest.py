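"""Shared fixtures: a small synthetic cohort exercised by most modules."""

import pytest
from hypothesis import HealthCheck, settings

from pvsignal import SimulationConfig, assemble_cases, generate
from pvsignal.faers_io import PPS_SYNONYMS, target_caseids

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_reports=600, seed=42, duplicate_rate=0.3)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def universe(small_tables):
    """All deduplicated cases plus the target-drug caseid set."""
    cases = assemble_cases(small_tables, restrict=False)
    return cases, target_caseids(cases, PPS_SYNONYMS)


@pytest.fixture(scope="session")
def target_cases(universe):
    cases, ids = universe
    return [c for c in cases if c.caseid in ids]
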
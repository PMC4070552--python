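"""Shared fixtures: one default synthetic cohort, reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from mitocovbias import (
    SimulationConfig,
    consensus_from_counts,
    generate_reference,
    simulate_site_profiles,
)

SEED = 0  # the suite's single fixed seed


@pytest.fixture(scope="session")
def default_cohort():
    """Full default simulation: reference, motifs, 11 profiles, truth."""
    cfg = SimulationConfig(seed=SEED)
    reference, motifs = generate_reference(cfg)
    profiles, truth = simulate_site_profiles(reference, cfg, motifs)
    return cfg, reference, motifs, profiles, truth


@pytest.fixture(scope="session")
def default_consensus(default_cohort):
    _, reference, _, profiles, _ = default_cohort
    return consensus_from_counts(profiles, np.array(list(reference.sequence)))
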
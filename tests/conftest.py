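"""Shared fixtures: the worked-example locus and small simulated mixtures."""

from __future__ import annotations

import numpy as np
import pytest

from snpmixlr import (
    LocusEvidence,
    LocusFrequencies,
    ReferenceProfile,
    SimulationConfig,
    sample_profiles,
    simulate_mixture,
)


@pytest.fixture
def worked_locus() -> tuple[LocusEvidence, LocusFrequencies]:
    """The published worked-example locus: reads 739/704, freqs 0.445/0.555."""
    ev = LocusEvidence("LOC1", 739, 704)
    fr = LocusFrequencies("LOC1", "C", "T", 0.445, 0.555)
    return ev, fr


@pytest.fixture(scope="session")
def balanced_2pm():
    """A balanced two-person mixture over 133 loci at depth 1000."""
    return simulate_mixture(
        SimulationConfig(L=133, n=2, ratios=(1.0, 1.0), depth=1000.0, seed=20211015)
    )


@pytest.fixture(scope="session")
def false_profiles(balanced_2pm):
    """Twenty non-contributor reference profiles drawn from the same panel."""
    rng = np.random.default_rng(424242)
    return sample_profiles(balanced_2pm.panel, 20, rng, prefix="FALSE")


def make_profile(sample_id: str, genotypes: dict[str, tuple[str, str]]) -> ReferenceProfile:
    return ReferenceProfile(sample_id, dict(genotypes))
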
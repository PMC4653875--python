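"""Shared fixtures: simulated study populations reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mafblup import FamilySpec, simulate_study_population

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_panel():
    """Scaled-down study population: 500 animals x 2000 SNPs, 4 chromosomes.

    U-shaped dense MAF spectrum, high-MAF-biased nested sparse arrays, and
    half-sib families (mean 3.1, max 24 progeny per sire).
    """
    return simulate_study_population(n_animals=500, n_snps=2000, seed=20260101)


@pytest.fixture(scope="session")
def small_panel():
    """Quick panel for plumbing tests: 120 animals x 600 SNPs."""
    return simulate_study_population(n_animals=120, n_snps=600, seed=42)


@pytest.fixture(scope="session")
def unrelated_panel():
    """Independent loci, no family structure (each animal its own sire)."""
    return simulate_study_population(
        n_animals=300,
        n_snps=800,
        ld_decay=0.0,
        family=FamilySpec(n_sires=300, mean_progeny=1.0),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
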
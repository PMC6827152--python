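"""Shared fixtures: small synthetic genomes and read sets.

Session-scoped so the heavier simulations run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from genomesurvey import GenomeSpec, ReadSimSpec, generate_genome, simulate_reads

K = 17
# coverage that puts the homozygous k-mer peak at ~70x for 150 bp reads
COV_FOR_70X = 70 * 150 / (150 - K + 1)


@pytest.fixture(scope="session")
def small_genome():
    """100 kb diploid genome at the default survey-like parameters."""
    return generate_genome(GenomeSpec(haploid_length=100_000, seed=7))


@pytest.fixture(scope="session")
def plain_genome():
    """100 kb genome with no repeats and no heterozygosity."""
    return generate_genome(
        GenomeSpec(haploid_length=100_000, het_rate=0.0, repeat_fraction=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def plain_reads(plain_genome):
    """Error-free 50x reads from the plain genome."""
    return simulate_reads(
        plain_genome, ReadSimSpec(coverage=50.0, error_rate=0.0, seed=13)
    )


@pytest.fixture(scope="session")
def survey_reads(small_genome):
    """Reads at ~70x k-mer depth with 0.3% errors from the default genome."""
    return simulate_reads(
        small_genome,
        ReadSimSpec(coverage=COV_FOR_70X, error_rate=0.003, seed=17),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
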
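"""Shared fixtures: small seeded synthetic inputs, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from barcodegap.community_sim import (
    GenomeFixtureParams,
    generate_genome_fixture,
    generate_panel,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_panel():
    """Six UT-like templates, enough to exercise assembly at exact-mode scale."""
    return generate_panel(n=6, seed=7)


@pytest.fixture(scope="session")
def small_reads(small_panel):
    """Error-free reads, 16 per template, both amplicon ends."""
    return simulate_reads(small_panel, reads_per_template=16, seed=3)


@pytest.fixture(scope="session")
def genome_fixture():
    """5 species x 3 genomes, designed intra 0.01 / inter 0.30 divergence."""
    return generate_genome_fixture(
        GenomeFixtureParams(intra_divergence=0.01, inter_divergence=0.30), seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
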
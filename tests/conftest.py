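"""Shared fixtures and hypothesis configuration."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_diploid_reads():
    """A 200 kb diploid at 2% heterozygosity with 30x error-free reads.

    Session-scoped so the spectrum tests share one simulation.
    """
    from genomesurvey.synthetic_data import (
        simulate_diploid,
        simulate_reads,
        simulate_reference,
    )

    ref = simulate_reference(200_000, 0.37, seed=11)
    dg = simulate_diploid(ref, 0.02, seed=12)
    reads = simulate_reads(dg, coverage=30, read_length=100, error_rate=0.0, seed=13)
    return dg, reads


@pytest.fixture(scope="session")
def planted_annotation():
    """Three scaffolds, 30 genes each, one 11-copy cluster at 95% identity."""
    from genomesurvey.synthetic_data import simulate_annotation

    return simulate_annotation(
        n_scaffolds=3, genes_per_scaffold=30, cluster_specs=[(11, 0.95)], seed=21
    )
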
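import pytest
from hypothesis import HealthCheck, settings

from epibench import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    """Two 200-kb contigs plus the lambda carrier."""
    return sd.simulate_genome(n_contigs=2, contig_length=200_000, seed=1)


@pytest.fixture(scope="session")
def genome_no_carrier():
    return sd.simulate_genome(n_contigs=2, contig_length=200_000, include_carrier=False, seed=1)


@pytest.fixture(scope="session")
def genes(genome):
    return sd.simulate_annotation(genome, 60, seed=2)


@pytest.fixture(scope="session")
def truth(genome, genes):
    return sd.simulate_truth_peaks(
        genome, n_peaks=50, frip=0.25, seed=3, genes=genes, at_promoters=0.5
    )
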
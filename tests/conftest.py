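import pytest
from hypothesis import HealthCheck, settings

from chromalink.genomic_model import GeneModel, GenomicInterval
from chromalink.synthetic_cohort import SimulationConfig, simulate_bundle

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial cohort used by several integration tests."""
    return SimulationConfig(
        seed=11,
        n_genes=80,
        n_patients=8,
        n_chromosomes=3,
        chromosome_length=4_000_000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """(annotation, cohort, truth, footprints, edges) for the small cohort."""
    return simulate_bundle(small_config)


@pytest.fixture
def toy_gene():
    """Plus-strand gene [20000, 30000) with exons [20000,21000) and [25000,26000)."""
    return GeneModel(
        "toy_gene",
        GenomicInterval("chr1", 20_000, 30_000),
        strand="+",
        exons=(
            GenomicInterval("chr1", 20_000, 21_000),
            GenomicInterval("chr1", 25_000, 26_000),
        ),
    )
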
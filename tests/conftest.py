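import pytest

from radmut.pipeline import analyze_cohort
from radmut.simulate import SimulationConfig, generate_trio_cohort

# Rates scaled up so a toy genome yields workable mutation counts; the
# default config keeps the study's real per-nt rates.
DEMO_KW = dict(
    genome_length=100_000,
    n_chromosomes=2,
    snv_rate=1e-6,
    indel_rate=3e-7,
    multisite_rate=3e-8,
    induced_deletion_count_mean=6.0,
    induced_multisite_count_mean=1.5,
    seed=7,
)


@pytest.fixture(scope="session")
def demo_config():
    return SimulationConfig(**DEMO_KW)


@pytest.fixture(scope="session")
def demo_cohort(demo_config):
    return generate_trio_cohort(demo_config)


@pytest.fixture(scope="session")
def demo_result(demo_cohort):
    return analyze_cohort(demo_cohort)
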
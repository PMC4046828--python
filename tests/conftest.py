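import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tagdge.reference import Transcript, build_reference_index
from tagdge.simulate import SimulationConfig, generate_transcriptome, plant_expression

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=300,
        length_min=150,
        length_max=600,
        n_stages=5,
        de_fraction=0.1,
        depth_per_stage=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return generate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_transcriptome):
    return plant_expression(small_config, [t.gene_id for t in small_transcriptome])


@pytest.fixture(scope="session")
def small_index(small_transcriptome):
    return build_reference_index(small_transcriptome, strand_mode="both")


def random_tag(rng: np.random.Generator) -> str:
    """A structurally valid 21-mer clean tag."""
    return "CATG" + "".join(rng.choice(list("ACGT"), size=17))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
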
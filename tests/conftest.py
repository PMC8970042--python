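import numpy as np
import pytest

from synfam.align import AlignmentParams
from synfam.pipeline import PipelineConfig, inputs_from_dataset, run_full_pipeline
from synfam.simulate import SyntheticConfig, generate_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, length))


@pytest.fixture(scope="session")
def small_dataset():
    """Two planted subgroups of 18 genes over the default six-species
    panel, with the default 20% degenerate mix."""
    return generate_family(SyntheticConfig(
        seed=11, n_subgroups=2, genes_per_subgroup=18,
        degenerate_fraction=0.2))


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(min_subgroup_size=15)


@pytest.fixture(scope="session")
def small_result(small_dataset, small_config):
    return run_full_pipeline(inputs_from_dataset(small_dataset), small_config)


@pytest.fixture(scope="session")
def default_params():
    return AlignmentParams()
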
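import numpy as np
import pytest

from ribolite.simdata import SimConfig, make_ground_truth, simulate, simulate_transcriptome


def small_sim_config(**overrides) -> SimConfig:
    base = dict(
        n_genes_per_class={"background": 5, "depleted_target": 2, "membrane_enriched": 2},
        mean_expression=40.0,
        n_replicates=2,
        contaminant_fraction=0.15,
        pcr_duplication_rate=0.3,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return simulate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return simulate(small_config, outdir)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_ground_truth(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
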
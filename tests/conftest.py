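import pytest

from apakit import discovery, pipeline
from apakit.simulate import SimConfig, generate_reference, simulate_tags


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg):
    """(genome, annotation, truth, tags) for the default config."""
    genome, annotation, truth = generate_reference(sim_cfg)
    tags = simulate_tags(genome, annotation, truth, sim_cfg)
    return genome, annotation, truth, tags


@pytest.fixture(scope="session")
def called(sim_bundle):
    genome, annotation, truth, tags = sim_bundle
    return discovery.call_peaks(tags, annotation)


@pytest.fixture(scope="session")
def counted(sim_bundle, called):
    _, _, _, tags = sim_bundle
    peaks, mats = discovery.build_count_matrices(called, tags, per_cell=True)
    return peaks, mats


@pytest.fixture(scope="session")
def pipeline_result(sim_bundle, sim_cfg):
    genome, annotation, truth, tags = sim_bundle
    return pipeline.run_pipeline(tags, annotation, genome,
                                 list(sim_cfg.cluster_ordering))
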
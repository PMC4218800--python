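import pytest

from mirforge.simulate import (
    GroundTruth,
    SimulationConfig,
    build_criterion_suite,
    build_ground_truth,
    simulate_srna_libraries,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, library_depth=3000, n_known_mirnas=15, n_novel_loci=3,
        n_background_loci=4, n_cleavage_sites=10,
    )


@pytest.fixture(scope="session")
def truth(small_config) -> GroundTruth:
    return build_ground_truth(small_config)


@pytest.fixture(scope="session")
def libraries(small_config, truth):
    return simulate_srna_libraries(small_config, truth)


@pytest.fixture(scope="session")
def criterion_suite():
    return build_criterion_suite(seed=5)
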
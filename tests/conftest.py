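import pytest

from driftlik.synth import ExperimentConfig, build_experiment_frames


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down neutral design for fast pipeline unit tests."""
    return ExperimentConfig.neutral(
        n_variant_sites=20, n_background_sites=300, seed=11
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return build_experiment_frames(small_config)
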
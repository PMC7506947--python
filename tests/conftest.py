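import numpy as np
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
def default_config():
    from throwspeed import GeneratorConfig

    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def study(default_config):
    """One default synthetic study (19 participants, 475 throws)."""
    from throwspeed import generate_study

    return generate_study(default_config)


@pytest.fixture(scope="session")
def truth_features(study):
    """Feature rows taken directly from the truth table (no signal path)."""
    from throwspeed.synthdata import features_from_truth

    return features_from_truth(study.truth)


@pytest.fixture(scope="session")
def signal_features(study):
    """Feature rows via the full signal path (segmentation + kinematics)."""
    from throwspeed.pipeline import RunConfig, extract_features

    return extract_features(study, RunConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
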
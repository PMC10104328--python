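import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from equigait.config import PipelineConfig
from equigait.pipeline import extract_cohort_features
from equigait.synthetic import FatigueEffectConfig, generate_cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small deterministic cohort with fatigue effects but no noise and no
    stride-to-stride variability: every feature equals its ground truth up
    to extraction error."""
    effects = FatigueEffectConfig(effects=FatigueEffectConfig.study_default().effects)
    return generate_cohort(6, 10, effects, seed=42)


@pytest.fixture(scope="session")
def zero_noise_features(zero_noise_cohort):
    cfg = PipelineConfig()
    return extract_cohort_features(zero_noise_cohort, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
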
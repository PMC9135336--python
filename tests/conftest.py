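import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pattern_cohort():
    """Small paired baseline/toe-in cohort at the generator's default
    noise, shared by learning/synthesis tests."""
    from toegait import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=42, n_subjects=12))


@pytest.fixture(scope="session")
def clean_cohort():
    """Deterministic cohort: no marker noise, no FPA jitter, fixed stance
    duration — toe-in cycles are exactly baseline + theta * g."""
    from toegait import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        seed=7,
        n_subjects=12,
        step_noise_mm=0.0,
        fpa_jitter_deg=0.0,
        stance_duration_jitter_s=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
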
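import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config():
    from archmech.synthetic import SimulationConfig

    return SimulationConfig(
        n_participants=2, seed=42,
        noise_torque_sd=0.0, noise_length_sd=0.0, noise_pennation_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    from archmech.synthetic import generate_cohort

    return generate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_cohort):
    from archmech.pipeline import PipelineConfig, process_cohort
    from archmech.synthetic import generate_architecture_scenes

    scenes = {t.participant_id: generate_architecture_scenes(t)
              for t, _ in noiseless_cohort}
    return process_cohort(noiseless_cohort, PipelineConfig(), scenes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
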
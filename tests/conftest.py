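import numpy as np
import pytest

from penumbra.simulate import MetricModel, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def small_sim_config(**overrides) -> SimulationConfig:
    """A desk-scale simulation config for fast pipeline tests."""
    defaults = dict(
        grid_shape=(32, 38, 32),
        voxel_size_mm=(2.0, 2.0, 2.0),
        n_case=16,
        n_control=10,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        grid_shape=(32, 38, 32),
        voxel_size_mm=(2.0, 2.0, 2.0),
        n_case=16,
        n_control=10,
        seed=7,
    )
    return cfg, simulate_cohort(cfg)


def null_metric_models() -> dict:
    """Metric models with all lesion effects switched off."""
    from penumbra.simulate import default_metric_models

    models = default_metric_models()
    return {k: MetricModel(v.mean, v.noise_sd, v.subject_sd, 0.0) for k, v in models.items()}
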
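import numpy as np
import pytest
from hypothesis import settings

from phenopipe.config import PipelineConfig, TemperatureResponseParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from phenopipe.pipeline import run_pipeline
from phenopipe.simulate import NoiseConfig, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def thermal_params() -> TemperatureResponseParams:
    """Wheat-like temperature response, explicit to silence the
    production-run warning."""
    return TemperatureResponseParams(explicit=True)


@pytest.fixture(scope="session")
def sim_clean():
    """Small noise-free virtual experiment (20 lines x 2 reps x 2
    treatments) with its ground truth."""
    cfg = SimulationConfig(seed=11, n_lines=20, n_reps=2)
    cfg.noise = NoiseConfig().off()
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def result_clean(sim_clean):
    """Pipeline result on the clean experiment, per-plant pot-weight
    correction so the water balance is deterministic per plant."""
    _, data = sim_clean
    cfg = PipelineConfig()
    cfg.plant_weight_correction = "per_plant"
    return run_pipeline(data, cfg, run_genetics=False)


@pytest.fixture(scope="session")
def sim_noisy():
    """Small experiment with the default observation noise."""
    cfg = SimulationConfig(seed=23, n_lines=30, n_reps=2)
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def result_noisy(sim_noisy):
    _, data = sim_noisy
    return run_pipeline(data, PipelineConfig(), run_genetics=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
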
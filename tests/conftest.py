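import numpy as np
import pandas as pd
import pytest

from glycodiet import (
    GP_COLUMNS,
    GlycanPeakMatrix,
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_effect_config() -> SimulationConfig:
    """Small multi-center cohort with a few calibrated trait effects."""
    return SimulationConfig(
        n_centers=3,
        subjects_per_center=30,
        n_plates=6,
        samples_per_plate=45,
        trait_time_effects={
            ("AF", "T1T2"): 0.35,
            ("LB", "T1T2"): 0.30,
            ("G3", "T2T3"): -0.25,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_effect_config):
    return simulate_cohort(small_effect_config)


@pytest.fixture(scope="session")
def pipeline_result(small_effect_config):
    return run_pipeline(PipelineConfig(simulation=small_effect_config, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(202)


def random_percent_matrix(
    rng: np.random.Generator, n: int, skew: bool = True
) -> GlycanPeakMatrix:
    """Random compositional %Area matrix (lognormal, closed to 100)."""
    logs = rng.normal(0.0, 1.0 if skew else 0.2, size=(n, 39))
    areas = np.exp(logs)
    percent = 100.0 * areas / areas.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(
        percent,
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        columns=list(GP_COLUMNS),
    )
    return GlycanPeakMatrix(frame, "percent")
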
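import os
import tempfile

import numpy as np
import pytest
from hypothesis import configuration, settings

# deterministic property-test runs; keep hypothesis caches out of the repo
configuration.set_hypothesis_home_dir(
    os.path.join(tempfile.gettempdir(), "hypothesis-home")
)
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from germtime import (
    ExperimentDataset,
    HydrothermalParams,
    SimulationDesign,
    TimeCourse,
    Treatment,
    predicted_fraction,
    simulate_experiment,
)

TRUTH = HydrothermalParams(theta_HT=1500.0, Tb=10.0, psi_b50=-1.2, sigma_psib=0.19)

FINE_SCHEDULE = tuple(np.arange(2.0, 602.0, 2.0))


@pytest.fixture(scope="session")
def truth_params() -> HydrothermalParams:
    return TRUTH


def model_exact_dataset(
    params: HydrothermalParams,
    temperatures=(15.0, 20.0, 25.0, 30.0),
    potentials=(0.0, -0.3, -0.6, -0.9, -1.2),
    n: int = 10000,
    schedule=FINE_SCHEDULE,
) -> ExperimentDataset:
    """Deterministic dataset whose counts follow the analytic germination
    surface exactly (up to count rounding) — no Monte-Carlo noise."""
    tcs = []
    for T in temperatures:
        for psi in potentials:
            cum = [round(n * predicted_fraction(params, psi, T, t)) for t in schedule]
            tcs.append(
                TimeCourse(Treatment(T, psi), "1", n, tuple(schedule), tuple(cum))
            )
    return ExperimentDataset(tcs)


@pytest.fixture(scope="session")
def exact_dataset(truth_params) -> ExperimentDataset:
    return model_exact_dataset(truth_params)


@pytest.fixture(scope="session")
def mc_dataset(truth_params) -> ExperimentDataset:
    """Paper-style stochastic design: 6 T × 5 Ψ × 3 dishes × 10 seeds, daily."""
    return simulate_experiment(truth_params, SimulationDesign(rng_seed=11))


@pytest.fixture()
def simple_tc() -> TimeCourse:
    return TimeCourse(
        treatment=Treatment(20.0, 0.0),
        replicate="1",
        n_sown=10,
        times=(24.0, 48.0, 72.0),
        cum_germinated=(2, 6, 9),
    )
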
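import dataclasses

import numpy as np
import pytest

import petquant as pq
from petquant.blood_input import HillFit, InputFunction, TriExpFit
from petquant.synthetic import RegionSpec, SimulationConfig


def make_canonical_input(delay: float = 0.0) -> InputFunction:
    """Deterministic analytic input function used across the test suite:
    tri-exponential plasma peaking at 1.5 min, Hill-decaying parent fraction,
    whole blood at 85% of total plasma."""
    amps = np.array([90.0, 15.0, 4.0])
    rates = np.array([2.5, 0.25, 0.012])
    peak_val = float(amps.sum())
    plasma = TriExpFit(1.5, amps, rates, np.array([0.0, 1.5]), np.array([0.0, peak_val]))
    wb = TriExpFit(1.5, amps * 0.85, rates, np.array([0.0, 1.5]), np.array([0.0, peak_val * 0.85]))
    hill = HillFit(0.12, 1.8, 35.0)
    return InputFunction(plasma=plasma, parent_fraction=hill, whole_blood=wb, delay=delay)


@pytest.fixture(scope="session")
def canonical_input() -> InputFunction:
    return make_canonical_input()


@pytest.fixture(scope="session")
def schedule45():
    return pq.default_schedule()


@pytest.fixture(scope="session")
def schedule120(schedule45):
    return schedule45.truncate(120.0)


@pytest.fixture(scope="session")
def canonical_params():
    # V_T = (0.3/0.15)(1 + 0.05/0.03) = 16/3
    return pq.KineticParameters(0.3, 0.15, 0.05, 0.03, 0.05)


@pytest.fixture(scope="session")
def canonical_tac(canonical_params, canonical_input, schedule120):
    return pq.simulate_2tcm(canonical_params, canonical_input, schedule120, label="canonical")


@pytest.fixture(scope="session")
def mini_config() -> SimulationConfig:
    """Small 4-region cohort for pipeline-level tests."""
    regions = (
        RegionSpec("frontal", 14.1, 100),
        RegionSpec("striatum", 15.6, 80),
        RegionSpec("cerebellum", 14.1, 100),
        RegionSpec("corpus_callosum", 8.0, 27),
    )
    return SimulationConfig(
        n_subjects=3, regions=regions, n_venous_subjects=2, image_shape=(8, 8, 8)
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    return pq.generate_cohort(mini_config, seed=7, with_images=True)


@pytest.fixture(scope="session")
def fast_kinetics_config(mini_config) -> SimulationConfig:
    """Noise-free variant with rapidly equilibrating kinetics, for estimator-
    equivalence checks where the slow-washout transient would dominate."""
    return dataclasses.replace(
        mini_config,
        noise_level=0.0,
        voxel_noise_level=0.0,
        blood_noise=0.0,
        k1_range=(0.45, 0.55),
        k3_range=(0.015, 0.025),
        k4_range=(0.09, 0.11),
        delay_range=(0.0, 0.0),
    )
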
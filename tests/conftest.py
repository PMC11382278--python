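"""Shared fixtures: calibrated toy parameters and sampled lambda ladders.

The heavy sampled fixtures are session-scoped so the estimator-validation
and statistics tests share one set of trajectories.  All randomness is
seeded; the master seed for the validation ladders is fixed once.
"""

import numpy as np
import pytest
from hypothesis import settings

import evbkit as ek
from evbkit.calibration import CalibrationTarget, calibrate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: master seed of the sampled validation fixtures
MASTER_SEED = 20240824

#: reference gas-phase energetics used for calibration (kcal/mol)
GAS_TARGETS = (1.28, -47.04)

#: sampling scale of the validation ladders: full 51-frame schedule,
#: 2e4 steps per frame, 10 independent replicas
LADDER_KW = dict(n_replicas=10, n_steps=20_000)


@pytest.fixture(scope="session")
def kt310() -> float:
    return ek.thermal_energy(310.0)


@pytest.fixture(scope="session")
def base_toy() -> ek.DiabaticSystem:
    """Uncalibrated default toy: equal 200 kcal/mol/A^2 wells 1 A apart."""
    return ek.make_marcus_system(200.0, 200.0, 0.0, 1.0, 0.0, ek.EVBParameters(0.0))


@pytest.fixture(scope="session")
def calibrated_params(base_toy, kt310) -> ek.EVBParameters:
    """(h_ij, alpha) fitted so the toy reproduces the gas-phase targets."""
    return calibrate(base_toy, CalibrationTarget(*GAS_TARGETS), kt310)


@pytest.fixture(scope="session")
def fixture_systems(base_toy, calibrated_params):
    """Three toy systems spanning symmetric, asymmetric and calibrated cases."""
    return {
        "symmetric": ek.make_marcus_system(
            200.0, 200.0, 0.0, 1.0, 0.0, ek.EVBParameters(10.0)
        ),
        "asymmetric": ek.make_marcus_system(
            150.0, 250.0, 0.0, 1.0, -5.0, ek.EVBParameters(8.0, 0.0)
        ),
        "calibrated": base_toy.with_params(calibrated_params),
    }


@pytest.fixture(scope="session")
def sampled_ladders(fixture_systems):
    """Full lambda-ladder sample sets for each fixture system."""
    out = {}
    for name, system in fixture_systems.items():
        out[name] = ek.run_ladder(
            system,
            ek.LambdaSchedule.uniform(51),
            base_seed=MASTER_SEED,
            **LADDER_KW,
        )
    return out
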
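import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pyrfate as pf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def space():
    return pf.pyrene_state_space()


@pytest.fixture(scope="session")
def normal():
    return pf.regime_parameters("normal")


@pytest.fixture(scope="session")
def wet():
    return pf.regime_parameters("wet")


@pytest.fixture(scope="session")
def dry():
    return pf.regime_parameters("dry")


@pytest.fixture(scope="session")
def all_regimes(normal, wet, dry):
    return {"normal": normal, "wet": wet, "dry": dry}


def constant_params(space, rates, u0, regime="const"):
    """Time-homogeneous pyrene-topology parameter set from four scalars."""
    topology = {
        "sorption": ("water", "sediment"),
        "desorption": ("sediment", "water"),
        "biodegradation": ("sediment", "biodegradation"),
        "volatilization": ("water", "volatilization"),
    }
    schedules = {
        name: pf.PiecewiseRateSchedule.from_breakpoints(
            [rates[name]], source=src, destination=dst
        )
        for name, (src, dst) in topology.items()
    }
    return pf.RegimeParameterSet(
        regime=regime, space=space, schedules=schedules, u0=pf.StateVector(u0)
    )
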
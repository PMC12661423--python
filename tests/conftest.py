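import warnings

import numpy as np
import pytest

from seedsim import (
    AirSchedule,
    Composition,
    DEFAULT_DRY_COMPOSITION,
    DiffusivityParams,
    IsothermParams,
    SimulationConfig,
)
from seedsim.isotherm import CouchmanKarasz


@pytest.fixture(autouse=True)
def _quiet_aw_diagnostics():
    """Silence the (expected) a_w > 1 diagnostics during solver runs."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="water activity", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def comp():
    """Hydrated whole-seed composition at the baseline initial moisture."""
    return Composition.from_dry_basis(0.367, dict(DEFAULT_DRY_COMPOSITION))


@pytest.fixture(scope="session")
def params_fh():
    return IsothermParams(model="FH", chi_ws=1.244)


@pytest.fixture(scope="session")
def params_ls():
    return IsothermParams(model="FH_LS", chi_ws=1.244)


@pytest.fixture(scope="session")
def rubbery_ck():
    """Low-T_g solid so most of the 25 degC isotherm sits above T_g.

    Used by parameter-recovery tests that need several rubbery rows.
    """
    return CouchmanKarasz(T_g_s=310.0)


@pytest.fixture(scope="session")
def baseline_schedule():
    return AirSchedule.constant(298.15, 0.30, 0.235)


@pytest.fixture(scope="session")
def quick_config():
    """Small, fast-converging configuration for solver property tests."""
    return SimulationConfig(
        N=5,
        R0=5e-4,
        isotherm=IsothermParams(model="FH_LS", chi_ws=1.244),
        diffusivity=DiffusivityParams(floor=1e-11),
        output_interval=600.0,
    )


@pytest.fixture(scope="session")
def baseline_run(quick_config, baseline_schedule):
    """One shared short drying run (2 h) for property assertions."""
    from seedsim import run

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run(quick_config, baseline_schedule, t_end=7200.0)


def approx_rel(a, b, rel):
    return abs(a - b) <= rel * abs(b)
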
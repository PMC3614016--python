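"""Shared fixtures: default parameters and pre-run experiment-condition traces.

The expensive mechanism simulations (pre-equilibration + integration) are
session-scoped so the many assertions against them pay the ODE cost once.
"""

import numpy as np
import pytest

from clampflow import (
    RateParameters,
    fit_multiexponential,
    loading_design,
    pulse_chase_design,
    reload_design,
    run_design,
    unload_trap_design,
)

BASELINE = 0.1
SCALE = 0.01


@pytest.fixture(scope="session")
def params():
    return RateParameters()


@pytest.fixture(scope="session")
def pulse_chase_params():
    # single-encounter parameter set (chase present)
    return RateParameters(k_conf=6.1, k_close=1.6, k_off_fast=0.43,
                          k_off_slow=0.058)


@pytest.fixture(scope="session")
def loading_trace(params):
    return run_design(loading_design(), params)


@pytest.fixture(scope="session")
def unload_trace(params):
    return run_design(unload_trap_design(), params)


@pytest.fixture(scope="session")
def unload_fit(unload_trace):
    return fit_multiexponential((unload_trace.time, unload_trace.signal), 2)


@pytest.fixture(scope="session")
def reload_trace(params):
    return run_design(reload_design(), params)


@pytest.fixture(scope="session")
def pulse_chase_trace(pulse_chase_params):
    return run_design(pulse_chase_design(), pulse_chase_params)
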
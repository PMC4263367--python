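"""Shared fixtures: parameter sets and the expensive conditioned states.

The heavyweight steady states (free-running and AP-clamped cAF variants at
400-ms CL) are computed once per session and shared by the protocol and
acceptance tests.
"""

import numpy as np
import pytest

from atrialternans.engine import run_to_steady_state
from atrialternans.itmap import ap_clamped_steady_state
from atrialternans.parameters import make_parameters

# a fixed, supra-threshold stimulus (A/F for 2 ms) keeps the suite
# deterministic and skips per-variant threshold bisection
STIM = 12.5


@pytest.fixture(scope="session")
def control_params():
    return make_parameters("control", "LA", stim_amplitude=STIM)


@pytest.fixture(scope="session")
def caf_params():
    return make_parameters("cAF", "LA", stim_amplitude=STIM)


@pytest.fixture(scope="session")
def caf_alt_params():
    return make_parameters("cAF", "LA", {"ki_Ca": 0.5}, stim_amplitude=STIM)


@pytest.fixture(scope="session")
def caf_alt_ss400(caf_alt_params):
    """Free-running cAF ki_Ca x0.5 period-2 steady state at 400-ms CL."""
    return run_to_steady_state(caf_alt_params, 400.0, max_beats=400)


@pytest.fixture(scope="session")
def clamped_ss400():
    """AP-clamped steady states of the cAF and cAF (ki_Ca x0.5) models."""
    out = {}
    for key, scales in (("cAF", {}), ("cAF_alt", {"ki_Ca": 0.5})):
        p = make_parameters("cAF", "LA", scales, stim_amplitude=0.0)
        out[key] = (p, ap_clamped_steady_state(p, 400.0, max_beats=300))
    return out


@pytest.fixture(scope="session")
def paced_control_state(control_params):
    """Control cell conditioned by 20 beats at 750-ms CL."""
    from atrialternans.engine import PacingSchedule, integrate
    from atrialternans.model import initial_state
    y = initial_state(control_params)
    sched = PacingSchedule([(750.0, 20)], stim_amplitude=STIM,
                           stim_duration=2.0)
    return integrate(y, control_params, sched, record_vars=("vm",)).final_state
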
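"""Derivative-function properties: equilibria, Nernst, charge and mass balance."""

import numpy as np
import pytest
from dataclasses import replace

from atrialternans import constants as c
from atrialternans.engine import PacingSchedule, integrate
from atrialternans.model import (compute_derivatives, initial_state,
                                 total_ca_content)
from atrialternans.parameters import make_parameters


def test_gates_at_steady_state_have_zero_derivative(control_params):
    """Any HH gate placed at its voltage-dependent x_inf has dx/dt = 0."""
    y = initial_state(control_params)
    dydt, _ = compute_derivatives(y, control_params)
    # initial_state puts every gate at equilibrium for the resting potential
    for i in c.RL_GATES:
        tau_scale = 1.0  # derivatives are (x_inf - x)/tau; zero at x = x_inf
        assert abs(dydt[i]) * tau_scale < 1e-10, c.STATE_NAMES[i]


def test_calcium_reversal_potential_matches_nernst(control_params):
    """The Ca2+ background current reverses at E_Ca = (RT/2F) ln(Cao/Caj);
    at ca_o = 1.8 mM, ca_j = 1e-4 mM and 310 K that is about +130.9 mV."""
    y = initial_state(control_params)
    y[c.I_CAJ] = 1e-4
    y[c.I_CASL] = 1e-4   # both background-current compartments at 0.1 µM

    def icabk(vm):
        y2 = y.copy()
        y2[c.I_VM] = vm
        _, cur = compute_derivatives(y2, control_params)
        return cur["i_cabk"]

    lo, hi = 100.0, 160.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if icabk(mid) < 0:
            lo = mid
        else:
            hi = mid
    e_ca = 0.5 * (lo + hi)
    expected = (c.R_GAS * 310.0 / (2 * c.FARADAY)) * np.log(1.8 / 1e-4)
    assert e_ca == pytest.approx(expected, abs=0.01)
    assert e_ca == pytest.approx(130.9, abs=0.2)


def test_charge_consistency_on_perturbed_states(caf_params):
    """Summing the reported currents reproduces -C_m dV/dt (to 1e-8 A/F)
    on randomly perturbed paced states, so the current set is complete."""
    rng = np.random.default_rng(7)
    y0 = initial_state(caf_params)
    for _ in range(25):
        y = y0.copy()
        y[c.I_VM] = rng.uniform(-90, 40)
        for i in (c.I_CAJ, c.I_CASL, c.I_CAI, c.I_CASR):
            y[i] *= rng.uniform(0.5, 2.0)
        for i in c.RL_GATES:
            y[i] = rng.uniform(0, 1)
        dydt, cur = compute_derivatives(y, caf_params)
        ncx = cur["i_ncx_junc"] + cur["i_ncx_sl"]
        total = (cur["i_na"] + cur["i_nal"] + cur["i_nabk"] + cur["i_cana"]
                 + cur["i_cal_junc"] + cur["i_cal_sl"] + cur["i_cak"]
                 + cur["i_cabk"] + cur["i_pca"] + cur["i_kr"] + cur["i_ks"]
                 + cur["i_k1"] + cur["i_kp"] + cur["i_to"] + cur["i_kur"]
                 + cur["i_clca"] + cur["i_clbk"] + ncx + cur["i_nak"])
        assert total == pytest.approx(cur["i_tot"], abs=1e-8)
        assert dydt[c.I_VM] == pytest.approx(-cur["i_tot"], abs=1e-8)


def test_ryr_occupancy_conserved_over_paced_beat(caf_params):
    """R, O, I and the implicit fourth state stay within [0, 1] and sum to
    one throughout a paced beat (conservation is structural; this guards
    the integrator update)."""
    y = initial_state(caf_params)
    sched = PacingSchedule([(400.0, 3)], stim_amplitude=12.5,
                           stim_duration=2.0)
    ts = integrate(y, caf_params, sched,
                   record_vars=("ryr_r", "ryr_o", "ryr_i"))
    r, o, i = (ts.data[k] for k in ("ryr_r", "ryr_o", "ryr_i"))
    ri = 1.0 - r - o - i
    for arr in (r, o, i, ri):
        assert arr.min() > -1e-9
        assert arr.max() < 1 + 1e-9
    assert np.max(np.abs(r + o + i + ri - 1.0)) < 1e-9


def test_total_calcium_conserved_in_closed_cell(caf_params):
    """With every sarcolemmal Ca2+ pathway silenced, total cell Ca2+
    (free + buffered + SR, volume-weighted) is conserved over a beat."""
    params = replace(caf_params, block_sarcolemmal_ca=True,
                     fast_buffers=False)
    y = initial_state(params)
    before = total_ca_content(y, params)
    sched = PacingSchedule([(400.0, 2)], stim_amplitude=12.5,
                           stim_duration=2.0)
    ts = integrate(y, params, sched, dt=0.01, record_vars=("vm",))
    after = total_ca_content(ts.final_state, params)
    assert after == pytest.approx(before, rel=1e-9)


def test_fast_equilibrium_buffers_change_vm_by_less_than_1mv(
        paced_control_state, control_params):
    """The rapid-buffering treatment of the membrane sites and CSQN alters
    the V_m trace by < 1 mV pointwise versus the explicit-buffer form.

    Each form is conditioned to its own rhythm (8 beats at a 2x-refined
    step, where the explicit kinetics are stable) before the compared beat.
    """
    sched_cond = PacingSchedule([(750.0, 8)], stim_amplitude=12.5,
                                stim_duration=2.0)
    sched = PacingSchedule([(750.0, 1)], stim_amplitude=12.5,
                           stim_duration=2.0)
    yf = integrate(paced_control_state.copy(), control_params, sched_cond,
                   dt=0.01, record_vars=("vm",)).final_state
    ts_fast = integrate(yf, control_params, sched, dt=0.01,
                        record_vars=("vm",))
    explicit = replace(control_params, fast_buffers=False)
    y = paced_control_state.copy()
    # populate the kinetic buffer slots at their equilibria
    kd_sll = c.KOFF_SLL / c.KON_SLL
    kd_slh = c.KOFF_SLH / c.KON_SLH
    y[c.I_SLLJ] = c.BMAX_SLLJ * y[c.I_CAJ] / (kd_sll + y[c.I_CAJ])
    y[c.I_SLHJ] = c.BMAX_SLHJ * y[c.I_CAJ] / (kd_slh + y[c.I_CAJ])
    y[c.I_SLLSL] = c.BMAX_SLLSL * y[c.I_CASL] / (kd_sll + y[c.I_CASL])
    y[c.I_SLHSL] = c.BMAX_SLHSL * y[c.I_CASL] / (kd_slh + y[c.I_CASL])
    pv = explicit.vector()
    y[c.I_CSQNB] = pv[c.P_BMAX_CSQN] * y[c.I_CASR] \
        / (pv[c.P_KD_CSQN] + y[c.I_CASR])
    ye = integrate(y, explicit, sched_cond, dt=0.01,
                   record_vars=("vm",)).final_state
    ts_exp = integrate(ye, explicit, sched, dt=0.01, record_vars=("vm",))
    dvm = np.abs(ts_fast.data["vm"] - ts_exp.data["vm"])
    assert dvm.max() < 1.0


def test_nonfinite_state_raises_named_diagnostic(control_params):
    y = initial_state(control_params)
    y[c.I_CASR] = -0.5
    with pytest.raises(FloatingPointError):
        compute_derivatives(y, control_params)


def test_validate_state_flags_bad_occupancy(control_params):
    from atrialternans.model import validate_state
    y = initial_state(control_params)
    validate_state(y, control_params)          # sane state passes
    y[c.I_RYRO] = 1.5
    with pytest.raises(ValueError):
        validate_state(y, control_params)
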
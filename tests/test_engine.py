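"""Pacing engine: schedules, quiescence, clamping exactness, dt refinement."""

import numpy as np
import pytest

from atrialternans import constants as c
from atrialternans.engine import (ClampSpec, PacingSchedule,
                                  build_ap_waveform, integrate,
                                  record_waveform)
from atrialternans.model import initial_state
from atrialternans import metrics as mx


class TestPacingSchedule:
    def test_total_beats_arithmetic(self):
        sched = PacingSchedule([(750, 20), (500, 74), (450, 74), (400, 74)])
        assert sched.total_beats == 242

    @pytest.mark.parametrize("stages", [[(0.0, 5)], [(-100, 5)], [(400, 0)]])
    def test_invalid_stages_rejected(self, stages):
        with pytest.raises(ValueError):
            PacingSchedule(stages)


class TestApWaveform:
    def test_boundary_values(self):
        w = build_ap_waveform(v_max=10, v_rest=-75, apd=200, cl=400, dt=0.02)
        assert w.max() == pytest.approx(10.0)
        t = np.arange(w.size) * 0.02
        assert np.all(w[t >= 200.0] == -75.0)   # diastolic segment
        assert w[0] == pytest.approx(10.0)      # peak at cycle start
        # monotone repolarization over the systolic segment
        sys = w[t < 200.0]
        assert np.all(np.diff(sys) <= 1e-12)

    def test_apd_must_be_shorter_than_cl(self):
        with pytest.raises(ValueError):
            build_ap_waveform(apd=400, cl=400)


def test_quiescent_cell_does_not_drift(control_params):
    """Zero stimulus: no upstroke, and once the construction transient has
    settled (20 quiescent beats) resting V_m drifts < 1 mV over 10 more."""
    y = initial_state(control_params)
    settle = PacingSchedule([(750.0, 20)], stim_amplitude=0.0,
                            stim_duration=2.0)
    y = integrate(y, control_params, settle, record_vars=("vm",)).final_state
    sched = PacingSchedule([(750.0, 10)], stim_amplitude=0.0,
                           stim_duration=2.0)
    ts = integrate(y, control_params, sched, record_vars=("vm",))
    vm = ts.data["vm"]
    assert vm.max() < -10.0
    assert vm.max() - vm.min() < 1.0


def test_clamped_state_trace_equals_waveform(caf_params):
    """A state variable clamped to a waveform reproduces it exactly at
    every recorded sample."""
    y = initial_state(caf_params)
    wave = build_ap_waveform(cl=400.0, dt=0.02)
    sched = PacingSchedule([(400.0, 3)], stim_amplitude=0.0,
                           stim_duration=2.0)
    ts = integrate(y, caf_params, sched, record_vars=("vm", "ca_i"),
                   clamp=ClampSpec("vm", wave), sample_dt=0.02)
    for b in range(3):
        np.testing.assert_array_equal(ts.beat("vm", b), wave)


def test_clamped_current_is_substituted(caf_params):
    """A flux clamped to zero stays zero in the recorded currents."""
    y = initial_state(caf_params)
    sched = PacingSchedule([(400.0, 2)], stim_amplitude=12.5,
                           stim_duration=2.0)
    n = int(round(400.0 / 0.02))
    ts = integrate(y, caf_params, sched, record_vars=("vm", "j_srcarel"),
                   clamp=ClampSpec("j_srcarel", np.zeros(n)))
    assert np.all(ts.data["j_srcarel"] == 0.0)


def test_dt_refinement_changes_apd_by_less_than_1ms(caf_params):
    """Halving the 20 µs step to 10 µs changes a cAF beat's APD90 at
    400-ms CL by < 1 ms."""
    cond = PacingSchedule([(750.0, 10), (400.0, 10)], stim_amplitude=12.5,
                          stim_duration=2.0)
    one = PacingSchedule([(400.0, 1)], stim_amplitude=12.5, stim_duration=2.0)
    apd = {}
    for dt in (0.02, 0.01):
        # condition each step size to its own orbit before comparing
        y = integrate(initial_state(caf_params), caf_params, cond, dt=dt,
                      record_vars=("vm",)).final_state
        ts = integrate(y, caf_params, one, dt=dt, record_vars=("vm",))
        apd[dt] = mx.compute_apd90(ts.data["vm"], ts.dt)
    assert abs(apd[0.02] - apd[0.01]) < 1.0


def test_record_waveform_is_full_resolution(caf_params):
    y = initial_state(caf_params)
    w = record_waveform(y, caf_params, 400.0, "vm", dt=0.02,
                        stim_amplitude=12.5)
    assert w.size == int(round(400.0 / 0.02))


def test_anm_invariant_to_recorded_variables(caf_params):
    """Recording extra variables (states or currents) leaves the APD series
    — hence ANM — bit-identical: observation does not perturb the run."""
    y = initial_state(caf_params)
    sched = PacingSchedule([(750.0, 4), (400.0, 12)], stim_amplitude=12.5,
                           stim_duration=2.0)
    a = integrate(y.copy(), caf_params, sched, record_vars=("vm",))
    b = integrate(y.copy(), caf_params, sched,
                  record_vars=("vm", "ca_i", "ca_sr", "i_ncx_junc"))
    np.testing.assert_array_equal(a.data["vm"], b.data["vm"])


def test_unknown_record_variable_rejected(control_params):
    y = initial_state(control_params)
    sched = PacingSchedule([(400.0, 1)])
    with pytest.raises(ValueError, match="unknown record"):
        integrate(y, control_params, sched, record_vars=("vm", "bogus"))
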
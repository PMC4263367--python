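"""SR release formulations: original luminal-regulated RyR, Sato-Bers CSQN
variant, SERCA and leak fluxes."""

import numpy as np
import pytest

from atrialternans import constants as c
from atrialternans.engine import (ClampSpec, PacingSchedule,
                                  build_ap_waveform, integrate)
from atrialternans.model import compute_derivatives, initial_state
from atrialternans.parameters import make_parameters


@pytest.fixture(scope="module")
def sb_params():
    return make_parameters("cAF", "LA", ryr_formulation="sato_bers",
                           stim_amplitude=12.5)


class TestOriginalRyr:
    def test_closed_channel_releases_nothing(self, caf_params):
        y = initial_state(caf_params)
        y[c.I_RYRO] = 0.0
        _, cur = compute_derivatives(y, caf_params)
        assert cur["j_srcarel"] == 0.0

    def test_release_linear_in_gradient(self, caf_params):
        y = initial_state(caf_params)
        y[c.I_RYRO] = 1e-3
        _, cur1 = compute_derivatives(y, caf_params)
        base = cur1["j_srcarel"]
        y2 = y.copy()
        # double the SR-to-cleft gradient at fixed open fraction
        y2[c.I_CASR] = y[c.I_CAJ] + 2.0 * (y[c.I_CASR] - y[c.I_CAJ])
        _, cur2 = compute_derivatives(y2, caf_params)
        assert cur2["j_srcarel"] == pytest.approx(2.0 * base, rel=1e-9)

    def test_reducing_ki_ca_prolongs_release(self, caf_params):
        """Halving the inactivation rate stretches the junctional Ca2+
        release event (duration above half-peak J_SRCarel)."""
        durations = {}
        for s in (1.0, 0.5):
            p = caf_params.rescaled({"ki_Ca": s}) if s != 1.0 else caf_params
            y = initial_state(p)
            sched = PacingSchedule([(750.0, 10), (400.0, 5)],
                                   stim_amplitude=12.5, stim_duration=2.0)
            y = integrate(y, p, sched, record_vars=("vm",)).final_state
            one = PacingSchedule([(400.0, 1)], 12.5, 2.0)
            ts = integrate(y, p, one, record_vars=("j_srcarel",))
            j = ts.data["j_srcarel"]
            durations[s] = (j > 0.5 * j.max()).sum() * ts.dt
        assert durations[0.5] > durations[1.0]


class TestSercaAndLeak:
    def test_forward_flux_half_saturates_at_kmf(self, control_params):
        y = initial_state(control_params)
        kmf = control_params.value("K_mf")
        y[c.I_CAI] = kmf
        y[c.I_CASR] = 1e-6      # make the reverse term negligible
        _, cur = compute_derivatives(y, control_params)
        vmax = control_params.value("V_maxSRCaP")
        # fwd = 1 at half-point: vmax * (1 - rev) / (2 + rev) ~ vmax/2... the
        # GPV form gives vmax * fwd/(1+fwd+rev); at fwd == 1, rev ~ 0 -> vmax/2
        assert cur["j_serca"] == pytest.approx(vmax / 2.0, rel=1e-3)

    def test_leak_vanishes_at_equal_concentrations(self, control_params):
        y = initial_state(control_params)
        y[c.I_CASR] = y[c.I_CAJ]
        _, cur = compute_derivatives(y, control_params)
        assert cur["j_srleak"] == pytest.approx(0.0, abs=1e-15)


class TestSatoBers:
    def test_jsr_refills_with_tau_tr(self, sb_params):
        """After an instantaneous JSR depletion with the RyR shut, ca_jsr
        relaxes toward ca_nsr; the free-Ca relaxation follows tau_tr
        stretched by the instantaneous CSQN buffering factor."""
        y = initial_state(sb_params)
        y[c.I_RYRO] = 0.0
        y[c.I_CSQNB] = 0.6          # ca_nsr
        y[c.I_CASR] = 0.3           # depleted JSR
        dydt, cur = compute_derivatives(y, sb_params)
        pv = sb_params.vector()
        beta = 1.0 / (1.0 + pv[c.P_BMAX_CSQN] * pv[c.P_KD_CSQN]
                      / (pv[c.P_KD_CSQN] + 0.3) ** 2)
        expected = beta * (0.6 - 0.3) / pv[c.P_TAUTR]
        assert dydt[c.I_CASR] == pytest.approx(expected, rel=1e-6)
        assert cur["j_tr"] == pytest.approx((0.6 - 0.3) / 5.0, rel=1e-9)

    def test_release_uses_jsr_gradient(self, sb_params):
        y = initial_state(sb_params)
        y[c.I_RYRO] = 1e-3
        _, cur = compute_derivatives(y, sb_params)
        expected = 134.0 * 1e-3 * (y[c.I_CASR] - y[c.I_CAJ])
        assert cur["j_srcarel"] == pytest.approx(expected, rel=1e-9)

    def test_csqn_regulation_bounds(self, sb_params):
        """The CSQN-bound RyR fraction relaxes within [0, 1] and the bound
        CSQN concentration stays within [0, B_max] over paced beats."""
        y = initial_state(sb_params)
        sched = PacingSchedule([(750.0, 6)], stim_amplitude=12.5,
                               stim_duration=2.0)
        ts = integrate(y, sb_params, sched,
                       record_vars=("ryr_i", "ca_jsr", "ryr_o"))
        b = ts.data["ryr_i"]
        assert b.min() >= -1e-9 and b.max() <= 1 + 1e-9
        bound = 0.4 * ts.data["ca_jsr"] / (0.6 + ts.data["ca_jsr"])
        assert bound.min() >= 0.0 and bound.max() <= 0.4

    def test_assay_excludes_first_beat_for_this_formulation(self, sb_params):
        """The release-slope assay drops each run's first post-perturbation
        beat under the CSQN-regulated formulation, whose immediate response
        deviates from the later linear relaxation."""
        from atrialternans.itmap import release_slope_assay
        p = make_parameters("cAF", "LA", ryr_formulation="sato_bers",
                            stim_amplitude=0.0)
        _, pts = release_slope_assay(p, 400.0, n_perturbations=2, n_beats=4)
        assert pts.shape[0] == 2 * (4 - 1)     # first beats excluded


def test_sr_mass_balance_during_beat(caf_params):
    """d(SR content)/dt equals uptake minus release minus leak
    (volume-weighted) along a paced beat."""
    y = initial_state(caf_params)
    sched = PacingSchedule([(750.0, 5)], 12.5, 2.0)
    y = integrate(y, caf_params, sched, record_vars=("vm",)).final_state
    ts = integrate(y, caf_params, PacingSchedule([(750.0, 1)], 12.5, 2.0),
                   record_vars=("ca_sr", "j_serca", "j_srcarel", "j_srleak"),
                   sample_dt=0.02)
    pv = caf_params.vector()
    casr = ts.data["ca_sr"]
    bound = pv[c.P_BMAX_CSQN] * casr / (pv[c.P_KD_CSQN] + casr)
    total = casr + bound
    lhs = np.gradient(total, 0.02)
    rhs = ts.data["j_serca"] - ts.data["j_srcarel"] \
        - ts.data["j_srleak"] * c.V_MYO / c.V_SR
    resid = np.abs(lhs - rhs)
    # central differences on a 20 µs grid: tolerance set by curvature
    assert np.median(resid) < 1e-4
    assert resid.max() < 0.05 * max(np.abs(rhs).max(), 1e-9)
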
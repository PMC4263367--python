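"""Sweep enumeration and the stochastic-variation regression machinery."""

import numpy as np
import pandas as pd
import pytest

from atrialternans.sensitivity import (RegressionSpec, SweepSpec,
                                       run_regression, run_sweep)


class TestSweepSpec:
    def test_default_sweep_enumerates_282_runs(self):
        """20 parameters x 7 non-identity scales x 2 chambers plus the two
        chamber baselines."""
        assert len(SweepSpec().enumerate_runs()) == 282

    def test_fine_sweep_extends_enumeration(self):
        spec = SweepSpec(fine_parameter="ki_Ca")
        runs = spec.enumerate_runs()
        fine = [(p, s) for _, p, s in runs if p == "ki_Ca"]
        assert ("ki_Ca", 0.35) in fine          # a 5%-step-only value
        assert len(runs) > 282

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(scales=(0.5, -1.0))


def test_micro_sweep_records_anm_grid():
    """A reduced sweep (one parameter, one scale, one CL stage) produces a
    tidy grid with ANM per CL and no failures; identity scaling is covered
    by the baseline row."""
    spec = SweepSpec(parameters=("ki_Ca",), scales=(0.5,),
                     chambers=("LA",), coarse_cls=(400,), beats_per_cl=16,
                     min_cl=400.0)
    df = run_sweep(spec, "cAF")
    assert set(df["parameter"]) == {"baseline", "ki_Ca"}
    assert not df["lost_capture"].any()
    base = df[df.parameter == "baseline"].iloc[0]
    alt = df[df.parameter == "ki_Ca"].iloc[0]
    # halved RyR inactivation produces alternans at 400 ms; baseline does not
    assert alt["anm"] > 0.05
    assert base["anm"] < 0.05


class TestRegression:
    """The regression is exercised with an analytic threshold-CL surrogate:
    a known linear model in log scale factors plus exclusions."""

    @staticmethod
    def _surrogate(params):
        s = params.scales
        cl = 250.0 - 180.0 * np.log(s.get("ki_Ca", 1.0)) \
            + 90.0 * np.log(s.get("g_CaL", 1.0))
        return cl

    def test_recovers_known_coefficients(self):
        spec = RegressionSpec(n_samples=120, sigma=0.2,
                              parameters=("ki_Ca", "g_CaL", "g_Kr"))
        res = run_regression(spec, "cAF", seed=3, detector=self._surrogate)
        tab = res["coefficients"].set_index("parameter")
        assert tab.loc["ki_Ca", "coef"] == pytest.approx(-180.0, abs=1e-6)
        assert tab.loc["g_CaL", "coef"] == pytest.approx(90.0, abs=1e-6)
        assert tab.loc["g_Kr", "coef"] == pytest.approx(0.0, abs=1e-6)
        assert res["r2"] > 0.999

    def test_exclusion_rule_drops_extreme_thresholds(self):
        def wild(params):
            return self._surrogate(params) * 4 - 500   # pushes some out
        spec = RegressionSpec(n_samples=120, sigma=0.3,
                              parameters=("ki_Ca", "g_CaL"))
        res = run_regression(spec, "cAF", seed=5, detector=wild)
        assert res["n_excluded"] > 0
        assert res["n_used"] + res["n_excluded"] == 120

    def test_zero_variance_is_degenerate(self):
        spec = RegressionSpec(n_samples=60, parameters=("ki_Ca", "g_CaL"))
        res = run_regression(spec, "cAF", seed=1, detector=lambda p: 300.0)
        assert res["degenerate"]

    def test_seeded_reproducibility_and_sign_stability(self):
        spec = RegressionSpec(n_samples=100, parameters=("ki_Ca", "g_CaL"))
        a = run_regression(spec, "cAF", seed=11, detector=self._surrogate)
        b = run_regression(spec, "cAF", seed=11, detector=self._surrogate)
        pd.testing.assert_frame_equal(a["coefficients"], b["coefficients"])
        signs = []
        for seed in (1, 2, 3):
            r = run_regression(spec, "cAF", seed=seed,
                               detector=self._surrogate)
            t = r["coefficients"].set_index("parameter")
            signs.append((np.sign(t.loc["ki_Ca", "coef"]),
                          np.sign(t.loc["g_CaL", "coef"])))
        assert len(set(signs)) == 1

    def test_prediction_decomposition(self):
        spec = RegressionSpec(n_samples=100, parameters=("ki_Ca", "g_CaL"))
        res = run_regression(spec, "cAF", seed=7, detector=self._surrogate,
                             predict_for={"ki_Ca": 0.5, "g_CaL": 0.5})
        expected = self._surrogate(
            type("P", (), {"scales": {"ki_Ca": 0.5, "g_CaL": 0.5}})())
        assert res["prediction"] == pytest.approx(expected, abs=1.0)
        assert set(res["contributions"].index) == {"ki_Ca", "g_CaL"}

    def test_sample_floor_enforced(self):
        with pytest.raises(ValueError):
            RegressionSpec(n_samples=10)
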
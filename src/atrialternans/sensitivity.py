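"""One-at-a-time parameter sweeps and stochastic-variation regression.

The sweep scales each named parameter over 25–200% of its variant value and
records the alternans normalized magnitude (ANM) per pacing CL >= 300 ms —
the heat-map view of which ionic changes move alternans onset to rates near
rest.  The regression analysis perturbs all parameters jointly (lognormal
scale factors), computes each sample's alternans threshold CL, and fits a
multivariable linear regression of threshold CL on log scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as c
from . import metrics as mx
from .engine import run_ramp_protocol
from .parameters import ModelParameters, make_parameters

DEFAULT_PARAMS = tuple(c.TABLE1_BASELINE)
COARSE_SCALES = (0.25, 0.50, 0.75, 1.25, 1.50, 1.75, 2.00)
FINE_KICA_SCALES = tuple(np.round(np.arange(0.25, 1.0001, 0.05), 2))


@dataclass
class SweepSpec:
    parameters: tuple = DEFAULT_PARAMS
    scales: tuple = COARSE_SCALES
    # opt-in 5%-increment sweep of one parameter (ki_Ca in the heat maps)
    fine_parameter: str | None = None
    fine_scales: tuple = FINE_KICA_SCALES
    chambers: tuple = ("LA", "RA")
    min_cl: float = 300.0
    beats_per_cl: int = 74
    coarse_cls: tuple = (500, 450, 400, 350, 300)

    def __post_init__(self):
        for s in tuple(self.scales) + tuple(self.fine_scales or ()):
            if s <= 0:
                raise ValueError("scales must be positive")

    def enumerate_runs(self):
        """(chamber, parameter, scale) for every simulation of the sweep:
        each chamber's baseline plus every non-identity (parameter, scale)
        combination, plus the fine sweep of ``fine_parameter``."""
        runs = []
        for ch in self.chambers:
            runs.append((ch, None, 1.0))
            for p in self.parameters:
                for s in self.scales:
                    if s != 1.0:
                        runs.append((ch, p, float(s)))
        if self.fine_parameter is not None:
            for s in self.fine_scales:
                if s != 1.0 and (self.fine_parameter, float(s)) not in {
                        (p, s0) for _, p, s0 in runs}:
                    runs.append((self.chambers[0], self.fine_parameter,
                                 float(s)))
        return runs


@dataclass
class RegressionSpec:
    n_samples: int = 500
    sigma: float = 0.2               # lognormal sd of the scale factors
    parameters: tuple = DEFAULT_PARAMS
    exclude_below: float = 100.0     # ms
    exclude_above: float = 750.0     # ms
    log_scales: bool = True

    def __post_init__(self):
        if self.n_samples < 2 * len(self.parameters):
            raise ValueError("need n_samples >= 2x parameter count")


def _ramp_anm(params: ModelParameters, min_cl, beats_per_cl, coarse):
    try:
        per_cl, summary = run_ramp_protocol(
            params, min_cl=min_cl, beats_per_cl=beats_per_cl, coarse=coarse,
            record_vars=("vm",))
    except Exception as exc:   # individual failures recorded, sweep continues
        return None, repr(exc)
    return per_cl, None


def run_sweep(spec: SweepSpec, variant: str = "cAF",
              stim_amplitude: float | None = 12.5) -> pd.DataFrame:
    """Execute the one-at-a-time sweep; one row per (chamber, parameter,
    scale, CL) holding ANM, mean APD and failure flags.  Deterministic."""
    rows = []
    for chamber, pname, scale in spec.enumerate_runs():
        scales = {} if pname is None else {pname: scale}
        params = make_parameters(variant, chamber, scales,
                                 stim_amplitude=stim_amplitude)
        per_cl, err = _ramp_anm(params, spec.min_cl, spec.beats_per_cl,
                                spec.coarse_cls)
        if err is not None:
            rows.append({"chamber": chamber, "parameter": pname or "baseline",
                         "scale": scale, "cl": np.nan, "anm": np.nan,
                         "mean_apd": np.nan, "error": err,
                         "lost_capture": True})
            continue
        for cl, e in per_cl.items():
            rows.append({
                "chamber": chamber, "parameter": pname or "baseline",
                "scale": scale, "cl": cl,
                "anm": e.get("anm", np.nan),
                "mean_apd": e.get("mean_apd", np.nan),
                "error": None,
                "lost_capture": bool(e.get("lost_capture", False)),
            })
    return pd.DataFrame(rows)


def onset_cl_detector(params: ModelParameters, min_cl: float = 100.0,
                      beats_per_cl: int = 74) -> float:
    """Alternans threshold CL by the ramp protocol, searching below 300 ms
    in 10-ms steps until capture is lost; NaN when no CL qualifies."""
    per_cl, summary = run_ramp_protocol(params, min_cl=min_cl,
                                        beats_per_cl=beats_per_cl,
                                        record_vars=("vm",))
    anm_by_cl = {cl: e["anm"] for cl, e in per_cl.items()
                 if not e.get("lost_capture")}
    onset = mx.detect_onset_cl(anm_by_cl, min_cl=min_cl)
    return np.nan if onset is None else float(onset)


def run_regression(spec: RegressionSpec, variant: str = "control",
                   seed: int = 0, detector=None,
                   predict_for: dict | None = None):
    """Stochastic parameter variation + multivariable linear regression.

    ``detector`` maps a ModelParameters to an alternans threshold CL (ms);
    the default is the full ramp-protocol detector (expensive — pass a
    reduced one for desk-scale runs).  Returns a dict with the coefficient
    table (value, t-statistic, p-value), the samples, and — when
    ``predict_for`` gives a dict of scale factors (e.g. the cAF remodeling
    set) — the predicted threshold CL and its per-parameter decomposition.
    """
    rng = np.random.default_rng(seed)
    detector = detector or onset_cl_detector
    names = list(spec.parameters)
    X = np.exp(rng.normal(0.0, spec.sigma, size=(spec.n_samples, len(names))))
    y = np.empty(spec.n_samples)
    for i in range(spec.n_samples):
        params = make_parameters(variant, "LA",
                                 dict(zip(names, X[i])),
                                 stim_amplitude=12.5)
        y[i] = detector(params)
    keep = np.isfinite(y) & (y >= spec.exclude_below) \
        & (y <= spec.exclude_above)
    n_excluded = int((~keep).sum())
    Xk, yk = X[keep], y[keep]
    if np.ptp(yk) == 0 or len(yk) <= len(names) + 1:
        return {"degenerate": True, "n_excluded": n_excluded,
                "coefficients": None}
    F = np.log(Xk) if spec.log_scales else Xk
    A = np.column_stack([np.ones(len(F)), F])
    coef, res, rank, _ = np.linalg.lstsq(A, yk, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design after exclusions")
    resid = yk - A @ coef
    dof = len(yk) - A.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    from scipy import stats
    pval = 2 * stats.t.sf(np.abs(tstat), dof)
    table = pd.DataFrame({
        "parameter": ["intercept"] + names,
        "coef": coef, "se": se, "t": tstat, "p": pval,
    })
    out = {"degenerate": False, "coefficients": table,
           "n_excluded": n_excluded, "n_used": int(keep.sum()),
           "r2": 1.0 - (resid @ resid) / np.sum((yk - yk.mean()) ** 2),
           "samples": pd.DataFrame(X, columns=names).assign(threshold_cl=y)}
    if predict_for is not None:
        f = np.array([np.log(predict_for.get(n, 1.0)) if spec.log_scales
                      else predict_for.get(n, 1.0) for n in names])
        contrib = coef[1:] * f
        out["prediction"] = float(coef[0] + contrib.sum())
        out["contributions"] = pd.Series(contrib, index=names)
    return out
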
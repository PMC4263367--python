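"""Beat-to-beat (iterated-map) analysis of Ca2+-cycling stability.

Under an AP voltage clamp the Ca2+ subsystem decouples from membrane-voltage
dynamics and its beat-to-beat behaviour reduces to a two-variable map in the
pre-release SR load l_n and the total cell Ca2+ content T_n:

    l_{n+1} = l_n - r(l_n) + U_n            (release r, uptake U)
    T_{n+1} = T_n + I_n - E_n               (influx I, efflux E)

Linearizing with release slope m = dr/dl, uptake factor
u = dU/d(cytosolic Ca), and efflux factor kappa = dE/d(cytosolic Ca) — where
the per-beat cytosolic deviation is delta_r + delta_d with d_n = T_n - l_n —
gives the Jacobian

    [[(1-m)(1-u),  u], [kappa(1-m),  1-kappa]]

whose period-doubling boundary (eigenvalue -1) is

    m_thr = 1 + (2 - kappa) / (2 - 2u - kappa),     valid for u < 1 - kappa/2.

The system is stable (no Ca2+ alternans) for m < m_thr.  The threshold is
increasing in kappa — Ca2+ extrusion is protective — and all kappa-curves
converge to m_thr = 2 as u -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .engine import (DT_DEFAULT, ClampSpec, PacingSchedule,
                     build_ap_waveform, integrate, run_to_steady_state)
from .parameters import ModelParameters

V_SR_MYO = c.V_SR / c.V_MYO

_STATE_VARS = ("ca_sr", "ca_i", "ca_j", "ca_sl", "TnCL", "TnCHc", "CaM",
               "Myoc", "SRB", "SLLj", "SLLsl", "SLHj", "SLHsl")
_CUR_VARS = ("j_srcarel", "j_serca", "j_srleak", "i_cal_junc", "i_cal_sl",
             "i_cabk", "i_pca", "i_ncx_junc", "i_ncx_sl")


@dataclass
class IteratedMapParams:
    m: float
    u: float
    kappa: float
    threshold_m: float
    stable: bool
    r2: dict = field(default_factory=dict)
    quality_flag: bool = False
    alternating_fit: bool = False       # fitted near a 2-cycle, not a fixed point
    cl: float = np.nan


@dataclass
class BeatLedger:
    """Per-beat Ca2+ bookkeeping, all volume-weighted to cytosol (mM)."""
    load: np.ndarray       # pre-release total SR Ca2+ (free + CSQN-bound)
    release: np.ndarray    # integral of the RyR release flux over the beat
    uptake: np.ndarray     # integral of the SERCA flux
    leak: np.ndarray       # integral of the SR leak
    efflux: np.ndarray     # net sarcolemmal Ca2+ efflux
    nonsr: np.ndarray      # pre-beat cytosolic+membrane Ca2+ content

    def balance_residual(self) -> np.ndarray:
        """|delta-load - uptake + release + leak| per beat (mM)."""
        dl = np.diff(self.load)
        n = dl.size
        return np.abs(dl - (self.uptake[:n] - self.release[:n]
                            - self.leak[:n]))


def alternans_threshold(u: float, kappa: float,
                        strict: bool = False) -> float:
    """Release-slope threshold m_thr(u, kappa) for Ca2+ alternans.

    Outside the validity range (u in (0, 1 - kappa/2), kappa in [0, 2)) the
    value is still returned but flagged by raising only when ``strict``.
    """
    denom = 2.0 - 2.0 * u - kappa
    if denom <= 0 or not (0 <= kappa < 2):
        if strict:
            raise ValueError(f"(u={u}, kappa={kappa}) outside the validity "
                             "range of the threshold formula")
        return np.inf
    return 1.0 + (2.0 - kappa) / denom


def _beat_ledger_from_traces(ts, params: ModelParameters,
                             n_beats: int) -> BeatLedger:
    """Slice a multi-beat AP-clamped TraceSet into per-beat ledger entries."""
    dt = ts.dt
    p = params.vector()
    bmax, kd = p[c.P_BMAX_CSQN], p[c.P_KD_CSQN]
    b = {v: ts.beats(v) for v in ts.data}
    casr0 = b["ca_sr"][:, 0]
    load = (casr0 + bmax * casr0 / (kd + casr0)) * V_SR_MYO
    rel = np.trapezoid(b["j_srcarel"], dx=dt, axis=1) * V_SR_MYO
    upt = np.trapezoid(b["j_serca"], dx=dt, axis=1) * V_SR_MYO
    leak = np.trapezoid(b["j_srleak"], dx=dt, axis=1)
    i_ca_net = (b["i_cal_junc"] + b["i_cal_sl"] + b["i_cabk"] + b["i_pca"]
                - 2.0 * (b["i_ncx_junc"] + b["i_ncx_sl"]))
    # A/F integrated over ms, converted exactly as the kernel's ca ODEs
    eff = np.trapezoid(i_ca_net, dx=dt, axis=1) \
        * c.CMEM / (2.0 * c.FARADAY * c.V_MYO)
    cyt = (b["ca_i"] + b["TnCL"] + b["TnCHc"] + b["CaM"] + b["Myoc"]
           + b["SRB"])[:, 0]
    sl = (b["ca_sl"] + b["SLLsl"] + b["SLHsl"])[:, 0] * c.V_SL / c.V_MYO
    jn = (b["ca_j"] + b["SLLj"] + b["SLHj"])[:, 0] * c.V_JUNC / c.V_MYO
    return BeatLedger(load=load[:n_beats], release=rel[:n_beats],
                      uptake=upt[:n_beats], leak=leak[:n_beats],
                      efflux=eff[:n_beats], nonsr=(cyt + sl + jn)[:n_beats])


def _clamped_run(y0, params, cl, dt, n_beats, wave):
    sched = PacingSchedule([(cl, n_beats)], stim_amplitude=0.0,
                           stim_duration=params.stim_duration)
    ts = integrate(np.array(y0, float), params, sched, dt,
                   _STATE_VARS + _CUR_VARS, clamp=ClampSpec("vm", wave))
    return ts


def ap_clamped_steady_state(params: ModelParameters, cl: float,
                            dt: float = DT_DEFAULT, state=None,
                            max_beats: int = 500,
                            ap_kwargs: dict | None = None):
    """Steady state under the analytic AP clamp at cycle length ``cl``."""
    wave = build_ap_waveform(cl=cl, dt=dt, **(ap_kwargs or {}))
    clamp = ClampSpec("vm", wave)
    y, info = run_to_steady_state(params, cl, dt, max_beats=max_beats,
                                  state=state, clamp=clamp, init_beats=30)
    return y, info, wave


def map_parameters(params: ModelParameters, cl: float, dt: float = DT_DEFAULT,
                   perturbation: float = 0.01, n_beats: int = 10,
                   state=None, ss=None, ap_kwargs: dict | None = None):
    """Estimate (m, u, kappa) by the ±1% SR-load perturbation protocol.

    From the AP-clamped steady state, [Ca2+]_SR is perturbed by ±
    ``perturbation`` at the start of an even and of an odd beat (four runs)
    and the beat ledger is recorded for ``n_beats`` beats per run (40 beats
    total; the Sato-Bers variant drops each run's first beat, 36 beats).
    Deviations are taken against a parallel unperturbed run, which cancels
    the residual slow drift of the reference orbit.

    Returns ``(IteratedMapParams, BeatLedger)`` of the pooled runs.
    """
    if ss is not None:
        y, info, wave = ss
    else:
        y, info, wave = ap_clamped_steady_state(params, cl, dt, state=state,
                                                ap_kwargs=ap_kwargs)
    sato = params.ryr_formulation == "sato_bers"
    skip = 1 if sato else 0
    # parity-shifted reference starts
    ts1 = _clamped_run(y, params, cl, dt, 1, wave)
    starts = {"even": y, "odd": ts1.final_state}
    dm_r, dm_l, du_y, du_x, dk_y = [], [], [], [], []
    ledgers = []
    for parity, y0 in starts.items():
        ref = _beat_ledger_from_traces(
            _clamped_run(y0, params, cl, dt, n_beats, wave), params, n_beats)
        for sgn in (+1.0, -1.0):
            yp = np.array(y0, float)
            yp[c.I_CASR] *= 1.0 + sgn * perturbation
            led = _beat_ledger_from_traces(
                _clamped_run(yp, params, cl, dt, n_beats, wave), params,
                n_beats)
            ledgers.append(led)
            sl_ = slice(skip, n_beats)
            dl = (led.load - ref.load)[sl_]
            dr = (led.release - ref.release)[sl_]
            du = (led.uptake - ref.uptake)[sl_]
            de = (led.efflux - ref.efflux)[sl_]
            dd = (led.nonsr - ref.nonsr)[sl_]
            dm_l.append(dl)
            dm_r.append(dr)
            du_x.append(dr + dd)
            du_y.append(du)
            dk_y.append(de)
    dl = np.concatenate(dm_l)
    dr = np.concatenate(dm_r)
    dx = np.concatenate(du_x)
    du = np.concatenate(du_y)
    de = np.concatenate(dk_y)

    def _fit(x, yv):
        A = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        pred = A @ coef
        sst = np.sum((yv - yv.mean()) ** 2)
        r2 = 1.0 - np.sum((yv - pred) ** 2) / sst if sst > 0 else np.nan
        return float(coef[0]), float(r2)

    m, r2m = _fit(dl, dr)
    u, r2u = _fit(dx, du)
    kappa, r2k = _fit(dx, de)
    thr = alternans_threshold(u, kappa)
    r2 = {"m": r2m, "u": r2u, "kappa": r2k}
    quality = any((not np.isfinite(v)) or v < 0.95 for v in r2.values()) \
        or len(dl) < 36
    pars = IteratedMapParams(
        m=m, u=u, kappa=kappa, threshold_m=thr, stable=bool(m < thr),
        r2=r2, quality_flag=bool(quality),
        alternating_fit=bool(info.get("period") == 2), cl=cl)
    pooled = BeatLedger(*[np.concatenate([getattr(L, f) for L in ledgers])
                          for f in ("load", "release", "uptake", "leak",
                                    "efflux", "nonsr")])
    return pars, pooled


def release_slope_assay(params: ModelParameters, cl: float = 400.0,
                        n_perturbations: int = 4, spread: float = 0.01,
                        n_beats: int = 10, dt: float = DT_DEFAULT,
                        state=None, ss=None):
    """SR release-slope assay: perturb [Ca2+]_SR over a spread of factors
    at the start of a clamped beat and regress total release per beat on
    pre-release SR load (pooled over the relaxation beats).

    Returns ``(slope, points)`` with points an (n, 2) array of
    (load, release) pairs in cytosol-referred mM.  The Sato-Bers variant
    excludes each run's first post-perturbation beat.
    """
    if n_perturbations < 2:
        raise ValueError("need at least 2 perturbation levels")
    if spread <= 0:
        raise ValueError("degenerate perturbation spread")
    if ss is not None:
        y, info, wave = ss
    else:
        y, info, wave = ap_clamped_steady_state(params, cl, dt, state=state)
    sato = params.ryr_formulation == "sato_bers"
    skip = 1 if sato else 0
    facs = np.linspace(1.0 - spread, 1.0 + spread, n_perturbations)
    pts = []
    for f in facs:
        yp = np.array(y, float)
        yp[c.I_CASR] *= f
        led = _beat_ledger_from_traces(
            _clamped_run(yp, params, cl, dt, n_beats, wave), params, n_beats)
        pts.append(np.column_stack([led.load, led.release])[skip:])
    pts = np.concatenate(pts)
    if pts.shape[0] < 3 or np.ptp(pts[:, 0]) <= 0:
        raise ValueError("degenerate assay: fewer than 3 distinct points")
    slope = float(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])
    return slope, pts


def threshold_crossing_cl(params: ModelParameters, cl_start: float = 700.0,
                          cl_stop: float = 300.0, cl_step: float = 10.0,
                          dt: float = DT_DEFAULT, ss_beats: int = 500):
    """Sweep CL downward and return the longest CL at which the release
    slope meets the Eq.-type threshold (m >= m_thr), with the per-CL table.

    Steady states are warm-started from the previous CL.
    """
    rows = []
    ystart = None
    crossing = None
    cl = cl_start
    while cl >= cl_stop - 1e-9:
        y, info, wave = ap_clamped_steady_state(
            params, cl, dt, state=ystart,
            max_beats=ss_beats if ystart is None else 200)
        pars, _ = map_parameters(params, cl, dt, ss=(y, info, wave))
        rows.append(pars)
        ystart = y
        if not pars.stable and crossing is None:
            crossing = cl
            break
        cl -= cl_step
    return crossing, rows


def predict_vs_simulate(params: ModelParameters, cls, dt: float = DT_DEFAULT,
                        rel_threshold: float = 0.05):
    """Compare map-predicted stability against direct AP-clamped CaT
    alternans detection for each CL; returns rows and the largest-CL
    disagreement (or None)."""
    from . import metrics as mx
    rows = []
    disagree = None
    ystart = None
    for cl in cls:
        y, info, wave = ap_clamped_steady_state(
            params, cl, dt, state=ystart, max_beats=400)
        ystart = y
        pars, _ = map_parameters(params, cl, dt, ss=(y, info, wave))
        ts = _clamped_run(y, params, cl, dt, 12, wave)
        cats = mx.cat_series(ts)
        rel_alt = mx.alternans_magnitude(cats) / max(np.mean(cats[-10:]), 1e-12)
        observed = bool(rel_alt > rel_threshold)
        rows.append({"cl": cl, "m": pars.m, "u": pars.u, "kappa": pars.kappa,
                     "threshold": pars.threshold_m,
                     "stable_predicted": pars.stable,
                     "alternans_observed": observed})
        if observed == pars.stable and disagree is None:
            disagree = cl
    return rows, disagree
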
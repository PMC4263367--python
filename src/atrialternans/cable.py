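"""1D monodomain fiber: the 0.33 x 0.33 x 9.9 mm tissue strand.

The preparation's cross-section is far below the space constant, so the slab
reduces to a cable stimulated at the proximal end with a distal recording
electrode.  The monodomain equation is solved by operator splitting (per-node
ionic step, then explicit diffusion with no-flux ends) at the cell engine's
20 µs step.  Conductivity enters as the diffusion coefficient
``D = sigma / (beta * C_m)`` with the cell's surface-to-volume ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from . import metrics as mx
from ._kernel import run_cable
from .engine import (DT_DEFAULT, SAMPLE_DT, PacingSchedule, TraceSet,
                     resolve_stimulus, run_to_steady_state)
from .parameters import ModelParameters

# surface-to-volume ratio (1/m) and specific membrane capacitance (F/m^2)
CM_AREA = 0.01
BETA_SV = (c.CMEM / CM_AREA) / (c.V_CELL * 1e-3)   # V_CELL litres -> m^3


@dataclass
class CableConfig:
    length: float = 9.9              # mm
    cross_section: tuple = (0.33, 0.33)   # mm (enters via stimulus span only)
    dx: float = 0.1                  # mm node spacing
    sigma: float = 0.2               # S/m isotropic bulk conductivity
    stim_span: float = 0.33          # mm of proximal nodes stimulated
    record_pos: float | None = None  # mm; default 0.5 mm from the distal end
    dt: float = DT_DEFAULT

    def __post_init__(self):
        n = self.length / self.dx
        if abs(n - round(n)) > 1e-9:
            raise ValueError("node spacing must divide the cable length")
        if self.sigma <= 0:
            raise ValueError("conductivity must be positive")
        if self.record_pos is None:
            self.record_pos = self.length - 0.5
        if not (0 <= self.record_pos <= self.length):
            raise ValueError("recording electrode outside the cable")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dx)) + 1

    @property
    def diffusion(self) -> float:
        """D in mm^2/ms."""
        d_m2_s = self.sigma / (BETA_SV * CM_AREA)    # m^2/s
        return d_m2_s * 1e3                          # mm^2/ms == 1e3 m^2/s

    @property
    def record_node(self) -> int:
        return int(round(self.record_pos / self.dx))


def run_cable_protocol(config: CableConfig, params: ModelParameters,
                       schedule: PacingSchedule, init_state=None,
                       sample_dt: float = SAMPLE_DT, rec_nodes=None,
                       Y=None):
    """Pace the fiber from the proximal electrode.

    Returns ``(vm_nodes, ts, Y)``: recorded-node traces sampled at
    ``sample_dt``, a TraceSet at the recording electrode, and the full node
    state matrix (for continuing a ramp).  Nodes are initialized with the
    single-cell steady state at 750-ms CL unless ``init_state`` or ``Y`` is
    given.  Per-beat conduction failure at the recording electrode is
    flagged on the TraceSet.
    """
    dt = config.dt
    lam = config.diffusion * dt / config.dx ** 2
    if lam > 0.5:
        raise ValueError("diffusion number D*dt/dx^2 exceeds 0.5; refine dx "
                         "or dt")
    n = config.n_nodes
    if Y is None:
        if init_state is None:
            init_state, _ = run_to_steady_state(params, 750.0, dt,
                                                max_beats=60, init_beats=20)
        Y = np.tile(np.asarray(init_state, float), (n, 1))
    if rec_nodes is None:
        rec_nodes = np.arange(n, dtype=np.int64)
    else:
        rec_nodes = np.asarray(rec_nodes, dtype=np.int64)
    if config.record_node not in rec_nodes:
        rec_nodes = np.append(rec_nodes, config.record_node)
    n_stim_nodes = max(1, int(round(config.stim_span / config.dx)))
    stride = max(1, int(round(sample_dt / dt)))
    status = -1
    chunks = []
    for cl, n_beats in schedule.stages:
        n_samp = (int(round(cl / dt)) * n_beats + stride - 1) // stride
        out = np.empty((len(rec_nodes), n_samp))
        status = run_cable(Y, params.vector(), dt, cl, n_beats,
                           schedule.stim_amplitude, schedule.stim_duration,
                           n_stim_nodes, lam, stride, rec_nodes, out)
        chunks.append(out)
        if status >= 0:
            break
    vm_nodes = np.concatenate(chunks, axis=1)
    last_cl = schedule.stages[-1][0]
    beat_samples = int(round(last_cl / dt)) // stride
    irec = int(np.where(rec_nodes == config.record_node)[0][0])
    ts = TraceSet(dt=dt * stride, data={"vm": vm_nodes[irec]},
                  beat_samples=beat_samples, cl=last_cl,
                  final_state=Y[config.record_node].copy(),
                  meta={"params": params.to_dict(), "sigma": config.sigma,
                        "dx": config.dx, "aborted_step": int(status),
                        "rec_nodes": rec_nodes.tolist()})
    vb = ts.beats("vm")
    ts.captured = vb.max(axis=1) > -10.0
    return vm_nodes, ts, Y


def run_cable_ramp(config: CableConfig, params: ModelParameters,
                   stim_amplitude: float, min_cl: float = 300.0,
                   beats_per_cl: int = 74,
                   coarse=(500, 450, 400, 350, 300), fine_step: float = 10.0,
                   stop_at_onset: bool = False):
    """Clinical ramp pacing on the fiber; APD metrics from the recording
    electrode.  Mirrors the single-cell ramp driver.  With
    ``stop_at_onset`` the descending sweep ends at the first CL whose ANM
    is significant — by construction the longest qualifying CL."""
    init_state, _ = run_to_steady_state(params, 750.0, config.dt,
                                        max_beats=60, init_beats=20)
    sched0 = PacingSchedule([(750.0, 20)], stim_amplitude=stim_amplitude,
                            stim_duration=params.stim_duration)
    _, _, Y = run_cable_protocol(config, params, sched0,
                                 init_state=init_state,
                                 rec_nodes=[config.record_node])
    cls = [float(x) for x in coarse if x >= min_cl]
    x = (coarse[-1] if coarse else 300) - fine_step
    while x >= min_cl:
        cls.append(float(x))
        x -= fine_step
    per_cl = {}
    for cl in cls:
        sched = PacingSchedule([(cl, beats_per_cl)],
                               stim_amplitude=stim_amplitude,
                               stim_duration=params.stim_duration)
        _, ts, Y = run_cable_protocol(config, params, sched, Y=Y,
                                      rec_nodes=[config.record_node])
        if ts.meta["aborted_step"] != -1 or not ts.captured.all():
            per_cl[cl] = {"lost_capture": True}
            break
        apds = mx.apd_series(ts)
        per_cl[cl] = {
            "lost_capture": False,
            "apd_series": apds,
            "alternans_magnitude": mx.alternans_magnitude(apds),
            "mean_apd": float(np.mean(apds[-10:])),
            "anm": mx.compute_anm(apds),
        }
        if stop_at_onset and per_cl[cl]["anm"] > mx.ANM_THRESHOLD:
            break
    anm_by_cl = {cl: e["anm"] for cl, e in per_cl.items()
                 if not e.get("lost_capture")}
    onset = mx.detect_onset_cl(anm_by_cl, min_cl=min_cl)
    return per_cl, onset


def activation_times(vm_nodes: np.ndarray, dt: float,
                     t0: int = 0, t1: int | None = None) -> np.ndarray:
    """Per-node activation time (ms): instant of maximal dV/dt within the
    sample window [t0, t1)."""
    win = vm_nodes[:, t0:t1]
    dv = np.diff(win, axis=1)
    return (np.argmax(dv, axis=1) + t0) * dt


def measure_cv(vm_nodes: np.ndarray, dt: float, dx: float,
               beat_window=None) -> float:
    """Conduction velocity (m/s) from a linear fit of activation time vs
    distance over the central 50% of the cable.  NaN if conduction failed."""
    n = vm_nodes.shape[0]
    if beat_window is None:
        at = activation_times(vm_nodes, dt)
    else:
        at = activation_times(vm_nodes, dt, *beat_window)
    lo, hi = n // 4, n - n // 4
    if np.any(vm_nodes[lo:hi].max(axis=1) < -10.0):
        return np.nan
    x_mm = np.arange(lo, hi) * dx
    t_ms = at[lo:hi]
    if np.ptp(t_ms) <= 0:
        return np.nan
    slope = np.polyfit(t_ms, x_mm, 1)[0]    # mm/ms == m/s
    return float(slope)


def _cv_of_sigma(sigma, config, params, cl, init_state, stim_amp):
    cfg = CableConfig(length=config.length, dx=config.dx, sigma=sigma,
                      stim_span=config.stim_span,
                      record_pos=config.record_pos, dt=config.dt)
    sched = PacingSchedule([(cl, 2)], stim_amplitude=stim_amp,
                           stim_duration=params.stim_duration)
    vm_nodes, ts, _ = run_cable_protocol(cfg, params, sched,
                                         init_state=init_state)
    # second beat, clear of initialization transients
    spb = int(round(cl / ts.dt))
    return measure_cv(vm_nodes, ts.dt, cfg.dx, beat_window=(spb, 2 * spb))


def tune_conductivity(target_cv: float, params: ModelParameters,
                      config: CableConfig | None = None, cl: float = 600.0,
                      tol: float = 0.005, lo: float = 0.05, hi: float = 0.5,
                      stim_amplitude: float | None = None):
    """Bisect the bulk conductivity until |CV - target| < ``tol`` m/s.

    Returns ``(sigma, achieved_cv)``.  CV grows monotonically with sigma
    (square-root-like), so plain bisection on the bracket suffices.
    """
    config = config or CableConfig()
    amp = stim_amplitude if stim_amplitude is not None \
        else 2.0 * resolve_stimulus(params, config.dt)
    init_state, _ = run_to_steady_state(params, 750.0, config.dt,
                                        max_beats=60, init_beats=20)
    cv_lo = _cv_of_sigma(lo, config, params, cl, init_state, amp)
    cv_hi = _cv_of_sigma(hi, config, params, cl, init_state, amp)
    # a very diffusive cable can fail to capture from the fixed stimulus
    # span; shrink the upper bracket until conduction succeeds
    while np.isnan(cv_hi) and hi > 2 * lo:
        hi *= 0.8
        cv_hi = _cv_of_sigma(hi, config, params, cl, init_state, amp)
    if not (cv_lo <= target_cv <= cv_hi) or np.isnan(cv_lo) or np.isnan(cv_hi):
        if not np.isnan(cv_lo) and abs(cv_lo - target_cv) < tol:
            return lo, cv_lo
        if not np.isnan(cv_hi) and abs(cv_hi - target_cv) < tol:
            return hi, cv_hi
        raise RuntimeError(
            f"target CV {target_cv} m/s outside bracket "
            f"[{cv_lo:.3f}, {cv_hi:.3f}] m/s")
    sigma, cv = hi, cv_hi
    for _ in range(40):
        sigma = 0.5 * (lo + hi)
        cv = _cv_of_sigma(sigma, config, params, cl, init_state, amp)
        if np.isnan(cv) or cv < target_cv:
            lo = sigma
        else:
            hi = sigma
        if not np.isnan(cv) and abs(cv - target_cv) < tol:
            break
    return sigma, cv


def measure_cv_for_variant(sigma: float, params: ModelParameters,
                           config: CableConfig | None = None,
                           cl: float = 600.0,
                           stim_amplitude: float | None = None) -> float:
    """CV (m/s) of a variant at a fixed, externally supplied conductivity."""
    config = config or CableConfig()
    amp = stim_amplitude if stim_amplitude is not None \
        else 2.0 * resolve_stimulus(params, config.dt)
    init_state, _ = run_to_steady_state(params, 750.0, config.dt,
                                        max_beats=60, init_beats=20)
    return _cv_of_sigma(sigma, config, params, cl, init_state, amp)
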
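"""Single-cell protocol engine: pacing, ramp protocol, steady states, clamps.

All protocols integrate with a fixed 20 µs step (Rush-Larsen for gates);
traces are recorded at 0.1-ms resolution by default, while clamp waveforms
are captured and replayed at full integration resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from . import metrics as mx
from ._kernel import run_paced, CLAMP_NONE, CLAMP_STATE, CLAMP_CURRENT
from .model import initial_state, resolve_clamp_target
from .parameters import ModelParameters

DT_DEFAULT = 0.02       # ms, the integration step used throughout
SAMPLE_DT = 0.1         # ms, trace recording resolution


@dataclass
class PacingSchedule:
    """Ordered pacing stages ``(cycle length ms, beat count)``."""
    stages: list
    stim_amplitude: float = 12.5   # A/F
    stim_duration: float = 2.0     # ms

    def __post_init__(self):
        for cl, n in self.stages:
            if cl <= 0 or cl < self.stim_duration:
                raise ValueError(f"cycle length {cl} invalid")
            if n < 1:
                raise ValueError("beat counts must be >= 1")

    @property
    def total_beats(self) -> int:
        return int(sum(n for _, n in self.stages))


@dataclass
class ClampSpec:
    """Clamp one model variable to a per-cycle waveform.

    ``target`` is a state-variable name (buffers excluded) or one of the
    clampable currents/fluxes; ``waveform`` is sampled at the integration
    step over exactly one cycle.
    """
    target: str
    waveform: np.ndarray
    parity: str = "even"

    def __post_init__(self):
        resolve_clamp_target(self.target)   # raises for invalid targets
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1 or self.waveform.size < 2:
            raise ValueError("waveform must be a 1-D trace over one cycle")


@dataclass
class TraceSet:
    """Uniformly sampled traces plus beat bookkeeping."""
    dt: float                       # sample interval (ms)
    data: dict                      # name -> 1-D array
    beat_samples: int               # samples per beat
    cl: float
    final_state: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    captured: np.ndarray | None = None   # per-beat capture flags

    @property
    def time(self) -> np.ndarray:
        n = len(next(iter(self.data.values())))
        return np.arange(n) * self.dt

    @property
    def n_beats(self) -> int:
        return len(next(iter(self.data.values()))) // self.beat_samples

    def beat(self, name: str, k: int) -> np.ndarray:
        s = self.beat_samples
        return self.data[name][k * s:(k + 1) * s]

    def beats(self, name: str) -> np.ndarray:
        s = self.beat_samples
        arr = self.data[name]
        return arr[: (len(arr) // s) * s].reshape(-1, s)


def _clamp_args(clamp: ClampSpec | None, n_per_beat: int):
    if clamp is None:
        return CLAMP_NONE, 0, 0, np.zeros(1)
    kind, code, idx = resolve_clamp_target(clamp.target)
    wave = clamp.waveform
    if wave.size != n_per_beat:
        # clamp waveforms are stored at integration resolution; resample if
        # a coarser trace was supplied
        wave = np.interp(np.arange(n_per_beat) * (wave.size / n_per_beat),
                         np.arange(wave.size), wave)
    return kind, code, idx, np.ascontiguousarray(wave)


def integrate(state: np.ndarray, params: ModelParameters,
              schedule: PacingSchedule, dt: float = DT_DEFAULT,
              record_vars=("vm", "ca_i"), clamp: ClampSpec | None = None,
              sample_dt: float = SAMPLE_DT) -> TraceSet:
    """Integrate under a pacing schedule, returning recorded traces.

    The returned TraceSet concatenates all stages; ``beat_samples`` refers to
    the *last* stage's cycle length, so per-beat analysis is meaningful when
    the schedule has a single stage (the protocol drivers call per stage).
    A NaN state aborts with the last valid beat recorded in ``meta``.
    """
    if not record_vars:
        raise ValueError("record_vars must be non-empty")
    y = np.array(state, dtype=float)
    stride = max(1, int(round(sample_dt / dt)))
    state_names = [v for v in record_vars if v in c.STATE_INDEX]
    cur_names = [v for v in record_vars if v in c.CURRENT_INDEX]
    unknown = set(record_vars) - set(state_names) - set(cur_names)
    if unknown:
        raise ValueError(f"unknown record variables: {sorted(unknown)}")
    rec_state = np.array([c.STATE_INDEX[v] for v in state_names], dtype=np.int64)
    rec_cur = np.array([c.CURRENT_INDEX[v] for v in cur_names], dtype=np.int64)
    chunks = {v: [] for v in record_vars}
    status = -1
    for cl, n_beats in schedule.stages:
        n_per_beat = int(round(cl / dt))
        kind, code, idx, wave = _clamp_args(clamp, n_per_beat)
        n_samp = (n_per_beat * n_beats + stride - 1) // stride
        out_state = np.empty((len(rec_state), n_samp))
        out_cur = np.empty((max(len(rec_cur), 1), n_samp))
        try:
            status = run_paced(y, params.vector(), dt, cl, n_beats,
                               schedule.stim_amplitude, schedule.stim_duration,
                               kind, code, idx, wave, rec_state, rec_cur,
                               stride, out_state, out_cur[:len(rec_cur)])
        except (ZeroDivisionError, FloatingPointError, ValueError):
            # a numerically exploded state aborts the stage; recorded
            # samples up to the failure are preserved
            status = -2
        for i, v in enumerate(state_names):
            chunks[v].append(out_state[i])
        for i, v in enumerate(cur_names):
            chunks[v].append(out_cur[i])
        if status >= 0:
            break
    data = {v: np.concatenate(ch) for v, ch in chunks.items()}
    last_cl = schedule.stages[-1][0]
    beat_samples = int(round(last_cl / dt)) // stride
    ts = TraceSet(dt=dt * stride, data=data, beat_samples=beat_samples,
                  cl=last_cl, final_state=y,
                  meta={"params": params.to_dict(), "dt": dt,
                        "stim_amplitude": schedule.stim_amplitude,
                        "stim_duration": schedule.stim_duration,
                        "aborted_step": int(status)})
    if "vm" in data and clamp is None and schedule.stim_amplitude > 0:
        vb = ts.beats("vm")
        ts.captured = (vb.max(axis=1) > -10.0)
    return ts


# ---------------------------------------------------------------------------
# stimulus calibration
# ---------------------------------------------------------------------------
_THRESHOLD_CACHE: dict = {}


def find_stimulus_threshold(params: ModelParameters, cl: float = 750.0,
                            dt: float = DT_DEFAULT, duration: float = 2.0,
                            lo: float = 0.5, hi: float = 40.0,
                            tol: float = 0.25) -> float:
    """Diastolic threshold current (A/F) for a ``duration``-ms pulse, by
    bisection on single trial beats from a settled state."""
    settle = PacingSchedule([(cl, 5)], stim_amplitude=12.5, stim_duration=5.0)
    ts = integrate(initial_state(params), params, settle, dt, ("vm",))
    base = ts.final_state

    def captures(amp):
        sched = PacingSchedule([(cl, 1)], stim_amplitude=amp,
                               stim_duration=duration)
        t = integrate(base.copy(), params, sched, dt, ("vm",))
        return t.data["vm"].max() > -10.0

    if not captures(hi):
        raise RuntimeError("no capture at the upper stimulus bracket")
    if captures(lo):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def resolve_stimulus(params: ModelParameters, dt: float = DT_DEFAULT) -> float:
    """Stimulus amplitude: explicit if set, else 2x diastolic threshold."""
    if params.stim_amplitude is not None:
        return params.stim_amplitude
    key = (params.digest(), params.stim_duration, dt)
    if key not in _THRESHOLD_CACHE:
        _THRESHOLD_CACHE[key] = 2.0 * find_stimulus_threshold(
            params, dt=dt, duration=params.stim_duration)
    return _THRESHOLD_CACHE[key]


# ---------------------------------------------------------------------------
# steady states and protocols
# ---------------------------------------------------------------------------
_SLOW_STATES = np.array([c.I_NAJ, c.I_NASL, c.I_NAI, c.I_KI,
                         c.I_NABJ, c.I_NABSL], dtype=np.int64)


def run_to_steady_state(params: ModelParameters, cl: float,
                        dt: float = DT_DEFAULT, max_beats: int = 1000,
                        tol: float = 1e-4, state: np.ndarray | None = None,
                        clamp: ClampSpec | None = None,
                        init_beats: int = 20):
    """Pace at a fixed CL until the beat-boundary state converges.

    Convergence is tested on a period-2 orbit: the relative L-inf change of
    the state across two beats must fall below ``tol``.  The slowly loading
    Na+ pools (and the fixed K+) are excluded from the norm — intracellular
    Na+ creeps for thousands of beats at a rate irrelevant to Ca2+-cycling
    dynamics.  Returns ``(state, info)`` where ``info['period']`` is 1 or 2
    (alternans), with the even/odd boundary states under ``info['pair']``
    for period-2, and ``info['converged']`` False on hitting ``max_beats``.
    """
    amp = 0.0 if (clamp is not None and clamp.target == "vm") \
        else resolve_stimulus(params, dt)
    if state is None:
        y = initial_state(params)
        sched = PacingSchedule([(cl, init_beats)], stim_amplitude=amp,
                               stim_duration=params.stim_duration)
        y = integrate(y, params, sched, dt, ("vm",), clamp=clamp).final_state
    else:
        y = np.array(state, dtype=float)
    sched2 = PacingSchedule([(cl, 2)], stim_amplitude=amp,
                            stim_duration=params.stim_duration)
    prev = y.copy()
    converged = False
    beats = 0
    err = np.inf
    scale = np.maximum(np.abs(y), 1e-6)
    pair = None
    fast = np.setdiff1d(np.arange(c.N_STATE), _SLOW_STATES)
    for _ in range(max_beats // 2):
        ts = integrate(y, params, sched2, dt, ("vm",), clamp=clamp)
        y = ts.final_state
        beats += 2
        err = np.max(np.abs((y - prev) / scale)[fast])
        if err < tol:
            converged = True
            break
        prev = y.copy()
        scale = np.maximum(np.abs(y), 1e-6)
    # classify period-1 vs period-2: a genuine 2-cycle has a consecutive-beat
    # state difference far above the residual 2-beat drift (slow Na+ loading
    # continues for thousands of beats and must not read as alternans)
    sched1 = PacingSchedule([(cl, 1)], stim_amplitude=amp,
                            stim_duration=params.stim_duration)
    y_mid = integrate(y.copy(), params, sched1, dt, ("vm",), clamp=clamp
                      ).final_state
    y_2 = integrate(y_mid.copy(), params, sched1, dt, ("vm",), clamp=clamp
                    ).final_state
    d1 = np.max(np.abs(y_mid - y) / scale)
    d2 = np.max(np.abs(y_2 - y) / scale)
    period = 2 if (d1 > max(10.0 * d2, 1e-3)) else 1
    if period == 2:
        pair = (y.copy(), y_mid.copy())
    info = {"converged": converged, "beats": beats, "period": period,
            "pair": pair, "residual": float(err) if np.isfinite(err) else 0.0}
    return y, info


def run_ramp_protocol(params: ModelParameters, dt: float = DT_DEFAULT,
                      min_cl: float = 300.0, beats_per_cl: int = 74,
                      coarse=(500, 450, 400, 350, 300), fine_step: float = 10.0,
                      record_vars=("vm", "ca_i"), stop_at_onset: bool = False):
    """Clinical ramp pacing: 20 beats at 750-ms CL, then ``beats_per_cl``
    beats per CL from 500 ms in 50-ms steps to 300 ms, then ``fine_step``-ms
    steps until ``min_cl`` or loss of capture.

    Returns ``(per_cl, summary)``: a dict CL -> dict with the APD series,
    alternans magnitude, mean APD and ANM, plus a metrics.AlternansSummary.
    """
    amp = resolve_stimulus(params, dt)
    y = initial_state(params)
    init = PacingSchedule([(750.0, 20)], stim_amplitude=amp,
                          stim_duration=params.stim_duration)
    y = integrate(y, params, init, dt, ("vm",)).final_state
    cls = [float(x) for x in coarse if x >= min_cl]
    x = (coarse[-1] if coarse else 300) - fine_step
    while x >= min_cl:
        cls.append(float(x))
        x -= fine_step
    per_cl = {}
    for cl in cls:
        sched = PacingSchedule([(cl, beats_per_cl)], stim_amplitude=amp,
                               stim_duration=params.stim_duration)
        ts = integrate(y.copy(), params, sched, dt, record_vars)
        if ts.meta["aborted_step"] != -1:
            per_cl[cl] = {"lost_capture": True}
            break
        captured = ts.captured if ts.captured is not None else np.ones(1, bool)
        if not captured.all():
            per_cl[cl] = {"lost_capture": True}
            break
        apds = mx.apd_series(ts)
        entry = {
            "lost_capture": False,
            "apd_series": apds,
            "alternans_magnitude": mx.alternans_magnitude(apds),
            "mean_apd": float(np.mean(apds[-10:])),
            "anm": mx.compute_anm(apds),
        }
        if "ca_i" in record_vars:
            entry["cat_series"] = mx.cat_series(ts)
        per_cl[cl] = entry
        y = ts.final_state
        if stop_at_onset and entry["anm"] > mx.ANM_THRESHOLD:
            break
    anm_by_cl = {cl: e["anm"] for cl, e in per_cl.items()
                 if not e.get("lost_capture")}
    summary = mx.AlternansSummary(
        cl=sorted(anm_by_cl, reverse=True),
        magnitude=[per_cl[cl]["alternans_magnitude"]
                   for cl in sorted(anm_by_cl, reverse=True)],
        mean_apd=[per_cl[cl]["mean_apd"] for cl in sorted(anm_by_cl, reverse=True)],
        anm=[anm_by_cl[cl] for cl in sorted(anm_by_cl, reverse=True)],
        onset_cl=mx.detect_onset_cl(anm_by_cl, min_cl=min_cl),
    )
    return per_cl, summary


def build_ap_waveform(v_max: float = 10.0, v_rest: float = -75.0,
                      apd: float = 200.0, cl: float = 400.0,
                      dt: float = DT_DEFAULT) -> np.ndarray:
    """Analytic AP-like voltage-clamp waveform over one cycle.

    Elliptical repolarization from ``v_max`` at the cycle start to ``v_rest``
    at ``t = apd``, diastolic at ``v_rest`` thereafter:
    ``V(t) = v_rest + (v_max - v_rest) * sqrt(1 - (t/apd)^2)``.
    """
    if apd >= cl:
        raise ValueError("apd must be shorter than the cycle length")
    t = np.arange(int(round(cl / dt))) * dt
    v = np.full(t.shape, float(v_rest))
    m = t < apd
    v[m] = v_rest + (v_max - v_rest) * np.sqrt(1.0 - (t[m] / apd) ** 2)
    return v


def record_waveform(state: np.ndarray, params: ModelParameters, cl: float,
                    target: str, dt: float = DT_DEFAULT,
                    stim_amplitude: float | None = None) -> np.ndarray:
    """Record one beat of ``target`` at integration resolution, starting
    from ``state`` (a beat-boundary state)."""
    amp = stim_amplitude if stim_amplitude is not None \
        else resolve_stimulus(params, dt)
    sched = PacingSchedule([(cl, 1)], stim_amplitude=amp,
                           stim_duration=params.stim_duration)
    ts = integrate(np.array(state, dtype=float), params, sched, dt,
                   (target,), sample_dt=dt)
    return ts.data[target]


def clamp_variable_protocol(params: ModelParameters, cl: float, target: str,
                            parity: str = "even", dt: float = DT_DEFAULT,
                            n_beats: int = 50, ss=None):
    """Clamp ``target`` to its steady-state even- or odd-beat waveform for
    ``n_beats`` beats; report percent changes of APD and CaT alternans
    magnitudes versus the unclamped baseline.

    The steady state must be period-2 (alternans); the *even* beat is the
    one with the smaller CaT amplitude, matching the labelling convention of
    the clamp summaries.  ``ss`` may carry a precomputed
    ``run_to_steady_state`` result to avoid repeating the conditioning run.
    """
    if parity not in ("even", "odd"):
        raise ValueError("parity must be 'even' or 'odd'")
    amp = resolve_stimulus(params, dt)
    if ss is None:
        ss = run_to_steady_state(params, cl, dt)
    y0, info = ss
    sched11 = PacingSchedule([(cl, 12)], stim_amplitude=amp,
                             stim_duration=params.stim_duration)
    base = integrate(y0.copy(), params, sched11, dt, ("vm", "ca_i"))
    base_apd = mx.apd_series(base)
    base_cat = mx.cat_series(base)
    apd_mag0 = mx.alternans_magnitude(base_apd)
    cat_mag0 = mx.alternans_magnitude(base_cat)
    if info["period"] != 2 or cat_mag0 <= 0:
        raise ValueError("unclamped model shows no alternans at this CL; "
                         "nothing to clamp against")
    # identify the small-CaT (even) and large-CaT (odd) boundary states
    ya, yb = info["pair"]
    cat_a = mx.cat_series(integrate(ya.copy(), params,
                                    PacingSchedule([(cl, 1)], amp,
                                                   params.stim_duration),
                                    dt, ("vm", "ca_i")))[0]
    cat_b = mx.cat_series(integrate(yb.copy(), params,
                                    PacingSchedule([(cl, 1)], amp,
                                                   params.stim_duration),
                                    dt, ("vm", "ca_i")))[0]
    even_start, odd_start = (ya, yb) if cat_a <= cat_b else (yb, ya)
    src = even_start if parity == "even" else odd_start
    wave = record_waveform(src, params, cl, target, dt, stim_amplitude=amp)
    clamp = ClampSpec(target=target, waveform=wave, parity=parity)
    clamp_amp = 0.0 if target == "vm" else amp
    sched = PacingSchedule([(cl, n_beats)], stim_amplitude=clamp_amp,
                           stim_duration=params.stim_duration)
    clamped = integrate(src.copy(), params, sched, dt, ("vm", "ca_i"),
                        clamp=clamp)
    n_tail = 12
    tail = TraceSet(clamped.dt,
                    {k: v[-n_tail * clamped.beat_samples:]
                     for k, v in clamped.data.items()},
                    clamped.beat_samples, cl)
    if target == "vm":
        apd_mag1 = 0.0   # voltage is clamped; APD alternans is abolished
    else:
        apd_mag1 = mx.alternans_magnitude(mx.apd_series(tail))
    cat_mag1 = mx.alternans_magnitude(mx.cat_series(tail))
    return {
        "target": target,
        "parity": parity,
        "apd_change_pct": 100.0 * (apd_mag1 - apd_mag0) / apd_mag0,
        "cat_change_pct": 100.0 * (cat_mag1 - cat_mag0) / cat_mag0,
        "baseline": {"apd_mag": apd_mag0, "cat_mag": cat_mag0},
        "clamped": {"apd_mag": apd_mag1, "cat_mag": cat_mag1},
    }
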
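"""Per-beat and per-CL derived quantities: APD90, CaT amplitude, alternans.

Definitions follow the clinical-alternans conventions: APD is measured from
the time of maximal upstroke velocity to 90% repolarization of the
phase-II amplitude; alternans magnitude is the mean |ΔAPD| over the last 10
beat pairs; ANM (alternans normalized magnitude) divides by the mean APD of
the last 10 beats, with > 0.05 deemed significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ANM_THRESHOLD = 0.05


@dataclass
class BeatMetrics:
    """Derived quantities of one beat."""
    apd90: float                 # ms
    cat_amplitude: float         # µM
    diastolic_cai: float         # µM
    systolic_cai: float          # µM
    upstroke_time: float         # ms from beat start
    max_dvdt: float              # mV/ms
    sr_load_prerelease: float = np.nan   # mM
    int_ical: float = np.nan     # mC/F
    int_incx: float = np.nan     # mC/F


@dataclass
class AlternansSummary:
    """Per-CL alternans metrics plus the onset CL."""
    cl: list = field(default_factory=list)
    magnitude: list = field(default_factory=list)     # ms
    mean_apd: list = field(default_factory=list)      # ms
    anm: list = field(default_factory=list)
    onset_cl: float | None = None


def compute_apd90(vm: np.ndarray, dt: float,
                  phase2_window=(5.0, 100.0)) -> float:
    """APD90 of a single-beat V_m trace sampled at ``dt`` ms.

    Start time is the sample of maximal dV/dt.  The phase-II amplitude is
    (max V_m within ``phase2_window`` ms after the upstroke) minus the
    pre-stimulus diastolic V_m, which excludes the brief phase-0/1 spike
    from the repolarization reference.  Returns NaN if the beat has no
    upstroke or does not repolarize within the trace.
    """
    vm = np.asarray(vm, dtype=float)
    dvdt = np.diff(vm) / dt
    if dvdt.size == 0 or np.nanmax(dvdt) < 1.0:
        return np.nan
    iup = int(np.nanargmax(dvdt))      # steepest rise between iup and iup+1
    t_up = iup + 0.5
    v_dia = vm[:iup + 1].min() if iup > 0 else vm[0]
    i0 = iup + 1 + int(round(phase2_window[0] / dt))
    i1 = min(iup + 1 + int(round(phase2_window[1] / dt)), vm.size)
    if i0 >= vm.size:
        return np.nan
    v_p2 = vm[i0:i1].max() if i1 > i0 else vm[iup + 1]
    v90 = v_p2 - 0.9 * (v_p2 - v_dia)
    below = np.where(vm[i0:] <= v90)[0]
    if below.size == 0:
        return np.nan
    icross = i0 + below[0]
    # linear interpolation of the crossing instant
    if icross > 0 and vm[icross - 1] > v90:
        frac = (vm[icross - 1] - v90) / (vm[icross - 1] - vm[icross])
    else:
        frac = 0.0
    return (icross - 1 + frac - t_up) * dt


def beat_metrics(vm: np.ndarray, cai: np.ndarray, dt: float,
                 prev_cai: np.ndarray | None = None) -> BeatMetrics:
    """Metrics of one beat; ``prev_cai`` is the preceding beat's [Ca2+]_i
    trace, whose diastolic minimum anchors the CaT amplitude."""
    vm = np.asarray(vm, float)
    cai = np.asarray(cai, float)
    dvdt = np.diff(vm) / dt
    iup = int(np.nanargmax(dvdt)) if dvdt.size else 0
    half = len(cai) // 2
    dia_ref = np.min(prev_cai[half:]) if prev_cai is not None \
        else np.min(cai[:max(iup, 1)])
    return BeatMetrics(
        apd90=compute_apd90(vm, dt),
        cat_amplitude=(cai.max() - dia_ref) * 1e3,
        diastolic_cai=dia_ref * 1e3,
        systolic_cai=cai.max() * 1e3,
        upstroke_time=iup * dt,
        max_dvdt=float(dvdt.max()) if dvdt.size else np.nan,
    )


def apd_series(traceset) -> np.ndarray:
    """APD90 of every beat of a TraceSet (requires a recorded vm trace)."""
    beats = traceset.beats("vm")
    return np.array([compute_apd90(b, traceset.dt) for b in beats])


def cat_series(traceset) -> np.ndarray:
    """CaT amplitude (µM) per beat: peak [Ca2+]_i minus the minimum during
    the preceding diastolic interval (first beat: its own pre-upstroke
    minimum)."""
    beats = traceset.beats("ca_i")
    out = np.empty(len(beats))
    for k, b in enumerate(beats):
        if k == 0:
            dia = b[:max(len(b) // 10, 1)].min()
        else:
            dia = beats[k - 1][len(b) // 2:].min()
        out[k] = (b.max() - dia) * 1e3
    return out


def alternans_magnitude(series) -> float:
    """Mean |x_{k+1} - x_k| over the last 10 consecutive pairs (11 values)."""
    s = np.asarray(series, dtype=float)
    if s.size < 11:
        raise ValueError("need at least 11 beats to quantify alternans")
    tail = s[-11:]
    return float(np.mean(np.abs(np.diff(tail))))


def compute_anm(apd_series) -> float:
    """Alternans normalized magnitude: magnitude / mean APD (last 10 beats)."""
    s = np.asarray(apd_series, dtype=float)
    return alternans_magnitude(s) / float(np.mean(s[-10:]))


def detect_onset_cl(anm_by_cl: dict, threshold: float = ANM_THRESHOLD,
                    min_cl: float = 300.0):
    """Longest CL (>= ``min_cl``) whose ANM exceeds ``threshold``; None if
    none qualifies.  Not restricted to a contiguous run."""
    qualifying = [cl for cl, anm in anm_by_cl.items()
                  if cl >= min_cl and anm > threshold]
    return max(qualifying) if qualifying else None


def integrate_current(current: np.ndarray, dt: float,
                      signed: bool = False) -> float:
    """Per-beat integral of a current trace (A/F over ms -> mC/F).

    Unsigned by default: currents of fixed dominant sign are reported as
    positive charge moved, so sign conventions cannot silently flip
    comparisons; pass ``signed=True`` for the algebraic integral.
    """
    cur = np.asarray(current, dtype=float)
    return float(np.trapezoid(cur if signed else np.abs(cur), dx=dt))
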
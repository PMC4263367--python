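"""Single-myocyte model surface: state construction, derivatives, Ca2+ accounting.

The GPVm model describes a human atrial myocyte with four Ca2+ spaces
(junctional cleft, sub-sarcolemmal space, bulk cytosol, SR) and a Markov
ryanodine receptor.  :func:`compute_derivatives` is the pure derivative
function over the flat state vector; protocol drivers live in
:mod:`.engine`.
"""

from __future__ import annotations

import numpy as np

from . import constants as c
from ._kernel import eval_cell, CLAMP_NONE, CLAMP_STATE, CLAMP_CURRENT
from .parameters import ModelParameters


def initial_state(params: ModelParameters) -> np.ndarray:
    """A quiescent starting state with buffers at equilibrium.

    Protocols always condition the model by pacing (20 beats at 750-ms CL
    for the clinical ramp), so only rough plausibility matters here.
    """
    y = np.zeros(c.N_STATE)
    vm = -75.0
    y[c.I_VM] = vm
    naj = nasl = nai = 9.1
    caj, casl, cai = 1.8e-4, 1.1e-4, 9.0e-5
    casr = 0.5
    y[c.I_NAJ], y[c.I_NASL], y[c.I_NAI] = naj, nasl, nai
    y[c.I_KI] = c.KI
    y[c.I_CAJ], y[c.I_CASL], y[c.I_CAI] = caj, casl, cai
    # gates at their resting steady state
    p = params.vector()
    dydt = np.zeros(c.N_STATE)
    cur = np.zeros(c.N_CURRENT)
    xinf = np.zeros(c.N_STATE)
    xtau = np.ones(c.N_STATE)
    y[c.I_CASR] = casr
    if params.ryr_formulation == "sato_bers":
        y[c.I_CSQNB] = casr           # ca_nsr
        y[c.I_RYRO] = 0.0
        y[c.I_RYRI] = c.SATOBERS_KC / (c.SATOBERS_KC + casr)
    else:
        y[c.I_RYRR] = 0.9
        y[c.I_RYRO] = 1e-6
        y[c.I_RYRI] = 1e-6
        if not params.fast_buffers:
            y[c.I_CSQNB] = p[c.P_BMAX_CSQN] * casr / (p[c.P_KD_CSQN] + casr)
    eval_cell(y, p, 0.0, CLAMP_NONE, 0, 0.0, dydt, cur, xinf, xtau)
    for i in np.concatenate([c.RL_GATES, c.BUFFER_STATES]):
        if xtau[i] < 0 or (0 < xtau[i] < 1e11):
            y[i] = xinf[i]
    return y


def compute_derivatives(state: np.ndarray, params: ModelParameters,
                        clamp=None, t: float = 0.0, i_app: float = 0.0):
    """Time derivatives and the instantaneous current set.

    ``clamp`` is an optional ``(target_name, value)`` pair; a clamped state
    variable reports a zero derivative and its value is used in every
    dependent expression; a clamped current/flux is substituted likewise.

    Returns ``(dydt, currents)`` with ``currents`` a name->value dict in A/F
    (membrane currents) or mM/ms (SR fluxes).  Raises ``FloatingPointError``
    naming the first non-finite current if the evaluation blows up.
    """
    y = np.asarray(state, dtype=float).copy()
    kind, code, idx, val = CLAMP_NONE, 0, 0, 0.0
    if clamp is not None:
        name, val = clamp
        kind, code, idx = resolve_clamp_target(name)
        if kind == CLAMP_STATE:
            y[idx] = val
    p = params.vector()
    dydt = np.zeros(c.N_STATE)
    cur = np.zeros(c.N_CURRENT)
    xinf = np.zeros(c.N_STATE)
    xtau = np.ones(c.N_STATE)
    try:
        eval_cell(y, p, i_app, kind, code if kind == CLAMP_CURRENT else idx,
                  val, dydt, cur, xinf, xtau)
    except Exception as exc:
        raise FloatingPointError(
            f"derivative evaluation failed on an unphysical state: {exc!r}"
        ) from exc
    currents = {n: float(cur[i]) for n, i in c.CURRENT_INDEX.items()}
    if not np.all(np.isfinite(cur)):
        bad = [n for n, v in currents.items() if not np.isfinite(v)]
        raise FloatingPointError(
            f"non-finite current(s) during derivative evaluation: {bad}")
    if not np.all(np.isfinite(dydt)):
        bad = [c.STATE_NAMES[i] for i in np.where(~np.isfinite(dydt))[0]]
        raise FloatingPointError(f"non-finite derivative(s) for state(s): {bad}")
    return dydt, currents


#: state variables that may not be clamped (buffer concentrations)
_UNCLAMPABLE = {c.STATE_NAMES[i] for i in c.BUFFER_STATES}


def resolve_clamp_target(name: str):
    """Map a clamp target name to (kind, current-code, state-index)."""
    if name in c.CLAMPABLE_CURRENTS:
        return CLAMP_CURRENT, c.CLAMPABLE_CURRENTS[name], 0
    if name in c.STATE_INDEX:
        if name in _UNCLAMPABLE:
            raise ValueError(f"{name!r} is a buffer concentration and is not "
                             "clampable")
        return CLAMP_STATE, 0, c.STATE_INDEX[name]
    raise ValueError(f"unknown clamp target {name!r}")


def csqn_bound(casr, params: ModelParameters):
    """Calsequestrin-bound Ca2+ (mM of SR volume) at luminal [Ca2+] ``casr``."""
    p = params.vector()
    if params.ryr_formulation == "original" and not params.fast_buffers:
        raise ValueError("explicit-buffer mode stores bound CSQN in the state")
    return p[c.P_BMAX_CSQN] * np.asarray(casr) / (p[c.P_KD_CSQN] + np.asarray(casr))


def sr_content(state: np.ndarray, params: ModelParameters) -> float:
    """Total SR Ca2+ (free + CSQN-bound), volume-weighted to cytosol (mM)."""
    y = np.asarray(state, dtype=float)
    p = params.vector()
    if params.ryr_formulation == "sato_bers":
        jsr = y[c.I_CASR]
        bound = p[c.P_BMAX_CSQN] * jsr / (p[c.P_KD_CSQN] + jsr)
        return float(((jsr + bound) * p[c.P_VJSR_FRAC]
                      + y[c.I_CSQNB] * p[c.P_VNSR_FRAC]) * c.V_CELL / c.V_MYO)
    casr = y[c.I_CASR]
    if params.fast_buffers:
        bound = p[c.P_BMAX_CSQN] * casr / (p[c.P_KD_CSQN] + casr)
    else:
        bound = y[c.I_CSQNB]
    return float((casr + bound) * c.V_SR / c.V_MYO)


def nonsr_ca_content(state: np.ndarray, params: ModelParameters) -> float:
    """Cytosolic + membrane-space Ca2+ (free and buffered), cytosol-weighted (mM)."""
    y = np.asarray(state, dtype=float)
    cyt = y[c.I_CAI] + y[c.I_TNCL] + y[c.I_TNCHC] + y[c.I_CAM] \
        + y[c.I_MYOC] + y[c.I_SRB]
    sl = (y[c.I_CASL] + y[c.I_SLLSL] + y[c.I_SLHSL]) * c.V_SL / c.V_MYO
    jn = (y[c.I_CAJ] + y[c.I_SLLJ] + y[c.I_SLHJ]) * c.V_JUNC / c.V_MYO
    return float(cyt + sl + jn)


def total_ca_content(state: np.ndarray, params: ModelParameters) -> float:
    """Whole-cell Ca2+ content, volume-weighted to cytosol volume (mM)."""
    return nonsr_ca_content(state, params) + sr_content(state, params)


def validate_state(state: np.ndarray, params: ModelParameters,
                   paced: bool = False):
    """Check the physical invariants of a state vector; raise on violation."""
    y = np.asarray(state, dtype=float)
    gates = np.concatenate([c.RL_GATES, [c.I_RYRR, c.I_RYRO, c.I_RYRI]])
    if np.any(y[gates] < -1e-9) or np.any(y[gates] > 1 + 1e-9):
        raise ValueError("gate or Markov occupancy outside [0, 1]")
    if params.ryr_formulation == "original":
        total = y[c.I_RYRR] + y[c.I_RYRO] + y[c.I_RYRI]
        if total > 1 + 1e-9:
            raise ValueError("RyR occupancies exceed unity")
    conc = [c.I_NAJ, c.I_NASL, c.I_NAI, c.I_KI, c.I_CAJ, c.I_CASL,
            c.I_CAI, c.I_CASR]
    if np.any(y[conc] <= 0):
        raise ValueError("non-positive ionic concentration")
    if paced and not (-100.0 <= y[c.I_VM] <= 60.0):
        raise ValueError("membrane potential outside [-100, 60] mV")
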
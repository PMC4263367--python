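"""Baseline constants of the modified Grandi-Pandit-Voigt (GPVm) human atrial model.

Values are transcribed from the published Grandi et al. 2011 human atrial
action potential model (Circ Res 109:1055-1066, "Human Atrial Action Potential
and Ca2+ Model: Sinus Rhythm and Chronic Atrial Fibrillation") and its
distributed MATLAB source.  The model here carries two modifications used for
tissue work: the fast Na+ current gating kinetics are replaced by the
Luo-Rudy dynamic (LRd) formulation, and calsequestrin may be treated with the
rapid-buffering (fast-equilibrium) approximation.

Units: time ms, voltage mV, concentrations mM, currents A/F, volumes L.
"""

import numpy as np

# ---------------------------------------------------------------------------
# physical constants and geometry
# ---------------------------------------------------------------------------
R_GAS = 8314.0        # J/(kmol*K)
FARADAY = 96485.0     # C/mol
TEMP = 310.0          # K (fixed; no temperature dependence)
FoRT = FARADAY / (R_GAS * TEMP)
CMEM = 1.10e-10       # F, whole-cell membrane capacitance

CELL_LENGTH = 100.0   # µm
CELL_RADIUS = 10.25   # µm
V_CELL = np.pi * CELL_RADIUS ** 2 * CELL_LENGTH * 1e-15   # L
V_MYO = 0.65 * V_CELL
V_SR = 0.035 * V_CELL
V_SL = 0.02 * V_CELL
V_JUNC = 0.0539 * 0.01 * V_CELL

# inter-compartment diffusion "conductances" (L/ms)
J_CA_JUNCSL = 1.0 / 1.2134e12
J_CA_SLMYO = 1.0 / 2.68510e11
J_NA_JUNCSL = 1.0 / (1.6382e12 / 3 * 100)
J_NA_SLMYO = 1.0 / (1.8308e10 / 3 * 100)

# current partitioning between junctional cleft and sub-sarcolemmal space
FJUNC = 0.11
FSL = 1.0 - FJUNC
FJUNC_CAL = 0.9
FSL_CAL = 0.1

# fixed ionic concentrations (mM)
CLI = 15.0
CLO = 150.0
KO = 5.4
NAO = 140.0
CAO = 1.8
MGI = 1.0
KI = 120.0            # intracellular K+ held constant, as in the source model

# ---------------------------------------------------------------------------
# state-vector layout (N_STATE slots).  The Sato-Bers variant reuses slots:
#   slot 14: RyR resting R (original)   | unused, held 0 (Sato-Bers)
#   slot 15: RyR open O                 | RyR open fraction O
#   slot 16: RyR inactivated I          | CSQN-bound RyR fraction b
#   slot 30: bound calsequestrin (mM)   | [Ca2+]_NSR (mM)
#   slot 31: [Ca2+]_SR (mM)             | [Ca2+]_JSR (mM)
# ---------------------------------------------------------------------------
I_VM = 0
I_M = 1
I_H = 2
I_J = 3
I_D = 4
I_F = 5
I_FCABJ = 6
I_FCABSL = 7
I_XTOF = 8
I_YTOF = 9
I_XKUR = 10
I_YKUR = 11
I_XKR = 12
I_XKS = 13
I_RYRR = 14
I_RYRO = 15
I_RYRI = 16        # Sato-Bers: CSQN-bound RyR fraction
I_NABJ = 17
I_NABSL = 18
I_TNCL = 19
I_TNCHC = 20
I_TNCHM = 21
I_CAM = 22
I_MYOC = 23
I_MYOM = 24
I_SRB = 25
I_SLLJ = 26
I_SLLSL = 27
I_SLHJ = 28
I_SLHSL = 29
I_CSQNB = 30       # Sato-Bers: ca_nsr
I_CASR = 31        # Sato-Bers: ca_jsr
I_NAJ = 32
I_NASL = 33
I_NAI = 34
I_KI = 35
I_CAJ = 36
I_CASL = 37
I_CAI = 38
I_ML = 39
I_HL = 40
N_STATE = 41

STATE_NAMES = [
    "vm", "m", "h", "j", "d", "f", "fcaBj", "fcaBsl", "xtof", "ytof",
    "xkur", "ykur", "xkr", "xks", "ryr_r", "ryr_o", "ryr_i",
    "NaBj", "NaBsl", "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom",
    "SRB", "SLLj", "SLLsl", "SLHj", "SLHsl", "csqnb", "ca_sr",
    "na_j", "na_sl", "na_i", "k_i", "ca_j", "ca_sl", "ca_i", "ml", "hl",
]
STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}
# aliases for the Sato-Bers SR layout
STATE_INDEX["ca_nsr"] = I_CSQNB
STATE_INDEX["ca_jsr"] = I_CASR
STATE_INDEX["csqn_bound_ryr"] = I_RYRI

# Hodgkin-Huxley-type gates advanced with the Rush-Larsen exponential update.
RL_GATES = np.array(
    [I_M, I_H, I_J, I_D, I_F, I_FCABJ, I_FCABSL, I_XTOF, I_YTOF,
     I_XKUR, I_YKUR, I_XKR, I_XKS, I_ML, I_HL], dtype=np.int64)

# Buffer states: linear ODEs in the bound concentration, also advanced
# exponentially (unconditionally stable at the 20 µs default step).
BUFFER_STATES = np.array(
    [I_NABJ, I_NABSL, I_TNCL, I_TNCHC, I_TNCHM, I_CAM, I_MYOC, I_MYOM,
     I_SRB, I_SLLJ, I_SLLSL, I_SLHJ, I_SLHSL, I_CSQNB], dtype=np.int64)

# ---------------------------------------------------------------------------
# current-set layout
# ---------------------------------------------------------------------------
CURRENT_NAMES = [
    "i_na", "i_nal", "i_nabk", "i_nak", "i_kr", "i_ks", "i_kp", "i_to",
    "i_kur", "i_k1", "i_clca", "i_clbk", "i_cal_junc", "i_cal_sl", "i_cak",
    "i_cana", "i_ncx_junc", "i_ncx_sl", "i_pca", "i_cabk",
    "j_srcarel", "j_serca", "j_srleak", "i_tot", "j_tr",
]
CURRENT_INDEX = {n: i for i, n in enumerate(CURRENT_NAMES)}
N_CURRENT = len(CURRENT_NAMES)

# currents/fluxes that may be clamped to a recorded waveform
CLAMPABLE_CURRENTS = {
    "j_srcarel": 1, "j_serca": 2, "j_srleak": 3,
    "i_ncx_junc": 4, "i_ncx_sl": 5, "i_cal_junc": 6, "i_cal_sl": 7,
}

# ---------------------------------------------------------------------------
# parameter-vector layout.  The first 20 slots are the named sensitivity
# parameters; the remainder are SR/RyR constants, variant flags and options.
# Every slot holds the fully resolved value (baseline × variant × user scale).
# ---------------------------------------------------------------------------
P_GNA = 0
P_GNAL = 1
P_GCAL = 2          # multiplies all three L-type permeabilities
P_TAUF = 3          # scale on tau_f(vm)
P_TAUFCA = 4        # scale on the fCa time constant (both rates / scale)
P_GK1 = 5
P_GKR = 6
P_GKS = 7
P_GKUR = 8
P_GTO = 9
P_IBARNCX = 10
P_KS = 11
P_KIM = 12
P_KOM = 13
P_KICA = 14
P_KOCA = 15
P_KLEAK = 16
P_VMAXSRCAP = 17
P_EC50SR = 18
P_KMF = 19
# SR geometry / CSQN
P_VSR_FRAC = 20
P_BMAX_CSQN = 21
P_KD_CSQN = 22
# Sato-Bers block
P_RYRFORM = 23      # 0 = original Markov RyR, 1 = Sato-Bers
P_KU = 24
P_KB = 25
P_TAUB = 26
P_TAUU = 27
P_TAUTR = 28
P_VJSR_FRAC = 29
P_VNSR_FRAC = 30
P_K34 = 31
# options
P_FASTBUF = 32      # 1 = fast-equilibrium calsequestrin (default), 0 = explicit
P_BLOCK_SLCA = 33   # 1 = zero all sarcolemmal Ca2+ pathways (mass-balance checks)
N_PARAM = 34

#: Table-1 sensitivity parameter names -> (vector slot, control/LA baseline).
#: ko_Ca carries units mM^-2 ms^-1; rates ms^-1; conductances mS/µF.
TABLE1_BASELINE = {
    "g_Na": (P_GNA, 23.0),
    "g_NaL": (P_GNAL, 0.0025),   # control applies a ×0 variant factor
    "g_CaL": (P_GCAL, 1.0),      # dimensionless multiplier on permeabilities
    "tau_f": (P_TAUF, 1.0),
    "tau_fCa": (P_TAUFCA, 1.0),
    "g_K1": (P_GK1, 0.0525),
    "g_Kr": (P_GKR, 0.035),
    "g_Ks": (P_GKS, 0.0035),
    "g_Kur": (P_GKUR, 0.045),
    "g_to": (P_GTO, 0.165),
    "Ibar_NCX": (P_IBARNCX, 3.15),
    "k_s": (P_KS, 25.0),
    "ki_m": (P_KIM, 0.005),
    "ko_m": (P_KOM, 0.06),
    "ki_Ca": (P_KICA, 0.5),
    "ko_Ca": (P_KOCA, 10.0),
    "k_leak": (P_KLEAK, 5.348e-6),
    "V_maxSRCaP": (P_VMAXSRCAP, 5.3114e-3),
    "ec_50SR": (P_EC50SR, 0.45),
    # atrial SERCA forward affinity is 2.5x the ventricular Km (0.615 µM),
    # giving the characteristically high atrial diastolic [Ca2+]i (~0.2 µM)
    "K_mf": (P_KMF, 2.5 * 0.246e-3),
}

#: chronic-AF remodeling: multiplicative factors on exactly the ten
#: parameters altered in the source model.
CAF_FACTORS = {
    "g_Na": 0.9,
    "g_NaL": 1.0,        # enabled via CONTROL_FACTORS (control has none)
    "g_CaL": 0.5,
    "g_to": 0.3,
    "g_Kur": 0.5,
    "g_K1": 2.0,
    "g_Ks": 2.0,
    "Ibar_NCX": 1.4,
    "ko_Ca": 3.0,
    "k_leak": 1.25,
}
#: control zeroes the late Na+ current (present only with cAF remodeling).
CONTROL_FACTORS = {"g_NaL": 0.0}
#: right-atrial chamber factors (LA is the reference chamber).
RA_FACTORS = {"g_Kur": 1.2}

#: Table-2 SR / RyR constants: original formulation.
TABLE2_ORIGINAL = {
    "V_SR/V_cell": (P_VSR_FRAC, 0.035),
    "B_max_csqn": (P_BMAX_CSQN, 2.6),
    "K_C": (P_KD_CSQN, 0.65),
}
#: Table-2 constants for the Sato-Bers replacement.  k_s and V_maxSRCaP are
#: re-pointed at the Table-1 slots when this formulation is selected.
TABLE2_SATOBERS = {
    "K_u": (P_KU, 15.0),
    "K_b": (P_KB, 0.015),
    "tau_b": (P_TAUB, 0.164),
    "tau_u": (P_TAUU, 312.0),
    "tau_tr": (P_TAUTR, 5.0),
    "V_JSR/V_cell": (P_VJSR_FRAC, 0.0035),
    "V_NSR/V_cell": (P_VNSR_FRAC, 0.0315),
    "k_34": (P_K34, 1.0),        # baseline closing rate; scalable like ki_Ca
}
SATOBERS_KS = 134.0
SATOBERS_VMAXSRCAP = 5.04e-2
SATOBERS_BMAX_CSQN = 0.4
SATOBERS_KC = 0.6

# cytosolic / membrane buffer constants (mM, ms^-1, mM^-1 ms^-1)
BMAX_NAJ = 7.561
BMAX_NASL = 1.65
KOFF_NA = 1e-3
KON_NA = 0.1e-3
BMAX_TNCLOW = 70e-3
KOFF_TNCL = 19.6e-3
KON_TNCL = 32.7
BMAX_TNCHIGH = 140e-3
KOFF_TNCHCA = 0.032e-3
KON_TNCHCA = 2.37
KOFF_TNCHMG = 3.33e-3
KON_TNCHMG = 3e-3
BMAX_CAM = 24e-3
KOFF_CAM = 238e-3
KON_CAM = 34.0
BMAX_MYOSIN = 140e-3
KOFF_MYOCA = 0.46e-3
KON_MYOCA = 13.8
KOFF_MYOMG = 0.057e-3
KON_MYOMG = 0.0157
BMAX_SR = 19 * 0.9e-3
KOFF_SR = 60e-3
KON_SR = 100.0
BMAX_SLLJ = 4.6e-3 * V_MYO / V_JUNC * 0.1
BMAX_SLLSL = 37.4e-3 * V_MYO / V_SL
BMAX_SLHJ = 1.65e-3 * V_MYO / V_JUNC * 0.1
BMAX_SLHSL = 13.4e-3 * V_MYO / V_SL
KOFF_SLL = 1300e-3
KON_SLL = 100.0
KOFF_SLH = 30e-3
KON_SLH = 100.0
KOFF_CSQN = 65.0
KON_CSQN = 100.0

# other fixed membrane-transport constants
GNAB = 0.597e-3
IBARNAK = 1.26
KMNAIP = 11.0
KMKO = 1.5
PNAK = 0.01833
GKP = 0.002
GCLCA = 0.0548
KDCLCA = 100e-3
GCLB = 9e-3
PCA_BASE = 2.7e-4
PNA_BASE = 0.75e-8
PK_BASE = 1.35e-7
KM_CAI = 3.59e-3
KM_CAO = 1.3
KM_NAI = 12.29
KM_NAO = 87.5
KSAT_NCX = 0.27
NU_NCX = 0.35
KDACT_NCX = 0.384e-3
IBAR_SLCAP = 0.0471
KM_PCA = 0.5e-3
GCAB = 6.0643e-4
KMR_SERCA = 1.7
HILL_SERCA = 1.787
MAX_SR = 15.0
MIN_SR = 1.0
# junctional Ca2+ trigger sensitivity of the Sato-Bers opening rate (mM)
SB_KCP = 0.2
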
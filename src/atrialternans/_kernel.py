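"""Compiled kernels: GPVm right-hand side, fixed-step cell and cable integrators.

The derivative evaluation is a single flat function over a 41-slot state
vector and a 33-slot resolved parameter vector (see :mod:`.constants`).
Integration uses a 20 µs default step with Rush-Larsen exponential updates
for Hodgkin-Huxley gates, exponential updates for the (linear) buffer ODEs
with mass-consistent Ca2+/Na+ exchange, and forward Euler elsewhere.

One model variable at a time may be clamped to a per-beat waveform: either a
state variable (held exactly at the waveform sample) or one of a set of
membrane currents / SR fluxes (substituted into every dependent expression).
"""

import numpy as np
from numba import njit

from .constants import (
    FoRT, CMEM, FARADAY, V_CELL, V_MYO, V_SR, V_SL, V_JUNC,
    J_CA_JUNCSL, J_CA_SLMYO, J_NA_JUNCSL, J_NA_SLMYO,
    FJUNC, FSL, FJUNC_CAL, FSL_CAL,
    CLI, CLO, KO, NAO, CAO, MGI, KI,
    I_VM, I_M, I_H, I_J, I_D, I_F, I_FCABJ, I_FCABSL, I_XTOF, I_YTOF,
    I_XKUR, I_YKUR, I_XKR, I_XKS, I_RYRR, I_RYRO, I_RYRI,
    I_NABJ, I_NABSL, I_TNCL, I_TNCHC, I_TNCHM, I_CAM, I_MYOC, I_MYOM,
    I_SRB, I_SLLJ, I_SLLSL, I_SLHJ, I_SLHSL, I_CSQNB, I_CASR,
    I_NAJ, I_NASL, I_NAI, I_KI, I_CAJ, I_CASL, I_CAI, I_ML, I_HL,
    N_STATE, N_CURRENT,
    P_GNA, P_GNAL, P_GCAL, P_TAUF, P_TAUFCA, P_GK1, P_GKR, P_GKS, P_GKUR,
    P_GTO, P_IBARNCX, P_KS, P_KIM, P_KOM, P_KICA, P_KOCA, P_KLEAK,
    P_VMAXSRCAP, P_EC50SR, P_KMF, P_VSR_FRAC, P_BMAX_CSQN, P_KD_CSQN,
    P_RYRFORM, P_KU, P_KB, P_TAUB, P_TAUU, P_TAUTR, P_VJSR_FRAC,
    P_VNSR_FRAC, P_K34, P_FASTBUF, P_BLOCK_SLCA,
    BMAX_NAJ, BMAX_NASL, KOFF_NA, KON_NA, BMAX_TNCLOW, KOFF_TNCL, KON_TNCL,
    BMAX_TNCHIGH, KOFF_TNCHCA, KON_TNCHCA, KOFF_TNCHMG, KON_TNCHMG,
    BMAX_CAM, KOFF_CAM, KON_CAM, BMAX_MYOSIN, KOFF_MYOCA, KON_MYOCA,
    KOFF_MYOMG, KON_MYOMG, BMAX_SR, KOFF_SR, KON_SR,
    BMAX_SLLJ, BMAX_SLLSL, BMAX_SLHJ, BMAX_SLHSL,
    KOFF_SLL, KON_SLL, KOFF_SLH, KON_SLH, KOFF_CSQN, KON_CSQN,
    GNAB, IBARNAK, KMNAIP, KMKO, PNAK, GKP, GCLCA, KDCLCA, GCLB,
    PCA_BASE, PNA_BASE, PK_BASE, KM_CAI, KM_CAO, KM_NAI, KM_NAO,
    KSAT_NCX, NU_NCX, KDACT_NCX, IBAR_SLCAP, KM_PCA, GCAB,
    KMR_SERCA, HILL_SERCA, MAX_SR, MIN_SR, SB_KCP,
)

# current-vector slots (kept in sync with constants.CURRENT_NAMES)
C_INA, C_INAL, C_INABK, C_INAK, C_IKR, C_IKS, C_IKP, C_ITO, C_IKUR, C_IK1, \
    C_ICLCA, C_ICLBK, C_ICALJ, C_ICALSL, C_ICAK, C_ICANA, C_INCXJ, C_INCXSL, \
    C_IPCA, C_ICABK, C_JREL, C_JSERCA, C_JLEAK, C_ITOT, C_JTR = range(25)

# clamp kinds
CLAMP_NONE = 0
CLAMP_STATE = 1
CLAMP_CURRENT = 2


@njit(cache=True, fastmath=True)
def eval_cell(y, p, i_app, clamp_kind, clamp_code, clamp_val,
              dydt, cur, xinf, xtau):
    """Fill dydt (true ODE derivatives), instantaneous currents, and the
    steady-state/time-constant pair for every exponentially updated state."""
    vm = y[I_VM]
    naj = y[I_NAJ]
    nasl = y[I_NASL]
    nai = y[I_NAI]
    ki = y[I_KI]
    caj = y[I_CAJ]
    casl = y[I_CASL]
    cai = y[I_CAI]
    sato = p[P_RYRFORM] > 0.5

    # Nernst potentials
    ena_junc = (1.0 / FoRT) * np.log(NAO / naj)
    ena_sl = (1.0 / FoRT) * np.log(NAO / nasl)
    ek = (1.0 / FoRT) * np.log(KO / ki)
    eca_junc = (1.0 / FoRT / 2.0) * np.log(CAO / caj)
    eca_sl = (1.0 / FoRT / 2.0) * np.log(CAO / casl)
    ecl = (1.0 / FoRT) * np.log(CLI / CLO)

    # ---- fast Na+ current (LRd kinetics) --------------------------------
    dv = vm + 47.13
    if np.abs(dv) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - np.exp(-0.1 * dv))
    bm = 0.08 * np.exp(-vm / 11.0)
    if vm >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp((vm + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * vm) / (1.0 + np.exp(-0.1 * (vm + 32.0)))
    else:
        ah = 0.135 * np.exp((80.0 + vm) / -6.8)
        bh = 3.56 * np.exp(0.079 * vm) + 3.1e5 * np.exp(0.35 * vm)
        aj = (-1.2714e5 * np.exp(0.2444 * vm) - 3.474e-5 * np.exp(-0.04391 * vm)) \
            * (vm + 37.78) / (1.0 + np.exp(0.311 * (vm + 79.23)))
        bj = 0.1212 * np.exp(-0.01052 * vm) / (1.0 + np.exp(-0.1378 * (vm + 40.14)))
    xinf[I_M] = am / (am + bm)
    xtau[I_M] = 1.0 / (am + bm)
    xinf[I_H] = ah / (ah + bh)
    xtau[I_H] = 1.0 / (ah + bh)
    xinf[I_J] = aj / (aj + bj)
    xtau[I_J] = 1.0 / (aj + bj)
    dydt[I_M] = am * (1.0 - y[I_M]) - bm * y[I_M]
    dydt[I_H] = ah * (1.0 - y[I_H]) - bh * y[I_H]
    dydt[I_J] = aj * (1.0 - y[I_J]) - bj * y[I_J]
    m3hj = y[I_M] ** 3 * y[I_H] * y[I_J]
    i_na_junc = FJUNC * p[P_GNA] * m3hj * (vm - ena_junc)
    i_na_sl = FSL * p[P_GNA] * m3hj * (vm - ena_sl)

    # ---- late Na+ current ----------------------------------------------
    aml = am
    bml = bm
    xinf[I_ML] = aml / (aml + bml)
    xtau[I_ML] = 1.0 / (aml + bml)
    dydt[I_ML] = aml * (1.0 - y[I_ML]) - bml * y[I_ML]
    hlinf = 1.0 / (1.0 + np.exp((vm + 91.0) / 6.1))
    xinf[I_HL] = hlinf
    xtau[I_HL] = 600.0
    dydt[I_HL] = (hlinf - y[I_HL]) / 600.0
    i_nal_junc = FJUNC * p[P_GNAL] * y[I_ML] ** 3 * y[I_HL] * (vm - ena_junc)
    i_nal_sl = FSL * p[P_GNAL] * y[I_ML] ** 3 * y[I_HL] * (vm - ena_sl)

    # ---- background Na+, Na/K pump -------------------------------------
    i_nabk_junc = FJUNC * GNAB * (vm - ena_junc)
    i_nabk_sl = FSL * GNAB * (vm - ena_sl)
    sigma = (np.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vm * FoRT)
                  + 0.0365 * sigma * np.exp(-vm * FoRT))
    i_nak_junc = FJUNC * IBARNAK * fnak * KO \
        / (1.0 + (KMNAIP / naj) ** 4) / (KO + KMKO)
    i_nak_sl = FSL * IBARNAK * fnak * KO \
        / (1.0 + (KMNAIP / nasl) ** 4) / (KO + KMKO)

    # ---- K+ currents ----------------------------------------------------
    gkr = p[P_GKR] * np.sqrt(KO / 5.4)
    xrss = 1.0 / (1.0 + np.exp(-(vm + 10.0) / 5.0))
    tauxr = 550.0 / (1.0 + np.exp((-22.0 - vm) / 9.0)) * 6.0 \
        / (1.0 + np.exp((vm + 11.0) / 9.0)) \
        + 230.0 / (1.0 + np.exp((vm + 40.0) / 20.0))
    xinf[I_XKR] = xrss
    xtau[I_XKR] = tauxr
    dydt[I_XKR] = (xrss - y[I_XKR]) / tauxr
    rkr = 1.0 / (1.0 + np.exp((vm + 74.0) / 24.0))
    i_kr = gkr * y[I_XKR] * rkr * (vm - ek)

    eks = (1.0 / FoRT) * np.log((KO + PNAK * NAO) / (ki + PNAK * nai))
    xsss = 1.0 / (1.0 + np.exp(-(vm + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + np.exp(-(vm + 2.436) / 14.12))
    xinf[I_XKS] = xsss
    xtau[I_XKS] = tauxs
    dydt[I_XKS] = (xsss - y[I_XKS]) / tauxs
    i_ks = p[P_GKS] * y[I_XKS] ** 2 * (vm - eks)

    kp_kp = 1.0 / (1.0 + np.exp(7.488 - vm / 5.98))
    i_kp = GKP * kp_kp * (vm - ek)

    xtoss = 1.0 / (1.0 + np.exp(-(vm + 1.0) / 11.0))
    tauxtof = 3.5 * np.exp(-((vm / 30.0) ** 2)) + 1.5
    ytoss = 1.0 / (1.0 + np.exp((vm + 40.5) / 11.5))
    tauytof = 25.635 * np.exp(-(((vm + 52.45) / 15.8827) ** 2)) + 24.14
    xinf[I_XTOF] = xtoss
    xtau[I_XTOF] = tauxtof
    xinf[I_YTOF] = ytoss
    xtau[I_YTOF] = tauytof
    dydt[I_XTOF] = (xtoss - y[I_XTOF]) / tauxtof
    dydt[I_YTOF] = (ytoss - y[I_YTOF]) / tauytof
    i_to = p[P_GTO] * y[I_XTOF] * y[I_YTOF] * (vm - ek)

    xkurss = 1.0 / (1.0 + np.exp((vm + 6.0) / -8.6))
    tauxkur = 9.0 / (1.0 + np.exp((vm + 5.0) / 12.0)) + 0.5
    ykurss = 1.0 / (1.0 + np.exp((vm + 7.5) / 10.0))
    tauykur = 590.0 / (1.0 + np.exp((vm + 60.0) / 10.0)) + 3050.0
    xinf[I_XKUR] = xkurss
    xtau[I_XKUR] = tauxkur
    xinf[I_YKUR] = ykurss
    xtau[I_YKUR] = tauykur
    dydt[I_XKUR] = (xkurss - y[I_XKUR]) / tauxkur
    dydt[I_YKUR] = (ykurss - y[I_YKUR]) / tauykur
    i_kur = p[P_GKUR] * y[I_XKUR] * y[I_YKUR] * (vm - ek)

    aki = 1.02 / (1.0 + np.exp(0.2385 * (vm - ek - 59.215)))
    bki = (0.49124 * np.exp(0.08032 * (vm + 5.476 - ek))
           + np.exp(0.06175 * (vm - ek - 594.31))) \
        / (1.0 + np.exp(-0.5143 * (vm - ek + 4.753)))
    kiss = aki / (aki + bki)
    i_k1 = p[P_GK1] * np.sqrt(KO / 5.4) * kiss * (vm - ek)

    # ---- Cl- currents ---------------------------------------------------
    i_clca_junc = FJUNC * GCLCA / (1.0 + KDCLCA / caj) * (vm - ecl)
    i_clca_sl = FSL * GCLCA / (1.0 + KDCLCA / casl) * (vm - ecl)
    i_clca = i_clca_junc + i_clca_sl
    i_clbk = GCLB * (vm - ecl)

    # ---- L-type Ca2+ current -------------------------------------------
    dv9 = vm + 9.0
    dss = 1.0 / (1.0 + np.exp(-dv9 / 6.0))
    if np.abs(dv9) < 1e-6:
        taud = 1.0 / (0.035 * 6.0)
    else:
        taud = dss * (1.0 - np.exp(-dv9 / 6.0)) / (0.035 * dv9)
    fss = 1.0 / (1.0 + np.exp((vm + 30.0) / 7.0)) \
        + 0.2 / (1.0 + np.exp((50.0 - vm) / 20.0))
    tauf = p[P_TAUF] / (0.0197 * np.exp(-((0.0337 * (vm + 25.0)) ** 2)) + 0.02)
    xinf[I_D] = dss
    xtau[I_D] = taud
    xinf[I_F] = fss
    xtau[I_F] = tauf
    dydt[I_D] = (dss - y[I_D]) / taud
    dydt[I_F] = (fss - y[I_F]) / tauf
    a_fca_j = 1.7 * caj / p[P_TAUFCA]
    a_fca_sl = 1.7 * casl / p[P_TAUFCA]
    b_fca = 11.9e-3 / p[P_TAUFCA]
    xinf[I_FCABJ] = a_fca_j / (a_fca_j + b_fca)
    xtau[I_FCABJ] = 1.0 / (a_fca_j + b_fca)
    xinf[I_FCABSL] = a_fca_sl / (a_fca_sl + b_fca)
    xtau[I_FCABSL] = 1.0 / (a_fca_sl + b_fca)
    dydt[I_FCABJ] = a_fca_j * (1.0 - y[I_FCABJ]) - b_fca * y[I_FCABJ]
    dydt[I_FCABSL] = a_fca_sl * (1.0 - y[I_FCABSL]) - b_fca * y[I_FCABSL]

    pca = p[P_GCAL] * PCA_BASE
    pna = p[P_GCAL] * PNA_BASE
    pk = p[P_GCAL] * PK_BASE
    # GHK driving terms; a tiny voltage offset sidesteps the 0/0 at vm = 0
    vms = vm if np.abs(vm) >= 1e-6 else 1e-6
    evfs = np.exp(vms * FoRT)
    evf2s = np.exp(2.0 * vms * FoRT)
    ibarca_j = pca * 4.0 * vms * FARADAY * FoRT \
        * (0.341 * caj * evf2s - 0.341 * CAO) / (evf2s - 1.0)
    ibarca_sl = pca * 4.0 * vms * FARADAY * FoRT \
        * (0.341 * casl * evf2s - 0.341 * CAO) / (evf2s - 1.0)
    ibark = pk * vms * FARADAY * FoRT \
        * (0.75 * ki * evfs - 0.75 * KO) / (evfs - 1.0)
    ibarna_j = pna * vms * FARADAY * FoRT \
        * (0.75 * naj * evfs - 0.75 * NAO) / (evfs - 1.0)
    ibarna_sl = pna * vms * FARADAY * FoRT \
        * (0.75 * nasl * evfs - 0.75 * NAO) / (evfs - 1.0)
    df = y[I_D] * y[I_F]
    i_cal_junc = FJUNC_CAL * ibarca_j * df * (1.0 - y[I_FCABJ]) * 0.45
    i_cal_sl = FSL_CAL * ibarca_sl * df * (1.0 - y[I_FCABSL]) * 0.45
    i_cak = ibark * df * (FJUNC_CAL * (1.0 - y[I_FCABJ])
                          + FSL_CAL * (1.0 - y[I_FCABSL])) * 0.45
    i_cana_junc = FJUNC_CAL * ibarna_j * df * (1.0 - y[I_FCABJ]) * 0.45
    i_cana_sl = FSL_CAL * ibarna_sl * df * (1.0 - y[I_FCABSL]) * 0.45
    if clamp_kind == CLAMP_CURRENT:
        if clamp_code == 6:
            i_cal_junc = clamp_val
        elif clamp_code == 7:
            i_cal_sl = clamp_val

    # ---- Na+/Ca2+ exchange ---------------------------------------------
    ka_junc = 1.0 / (1.0 + (KDACT_NCX / caj) ** 2)
    ka_sl = 1.0 / (1.0 + (KDACT_NCX / casl) ** 2)
    ev_nu = np.exp(NU_NCX * vm * FoRT)
    ev_num1 = np.exp((NU_NCX - 1.0) * vm * FoRT)
    s1j = ev_nu * naj ** 3 * CAO
    s2j = ev_num1 * NAO ** 3 * caj
    s3j = KM_CAI * NAO ** 3 * (1.0 + (naj / KM_NAI) ** 3) \
        + KM_NAO ** 3 * caj * (1.0 + caj / KM_CAI) \
        + KM_CAO * naj ** 3 + naj ** 3 * CAO + NAO ** 3 * caj
    i_ncx_junc = FJUNC * p[P_IBARNCX] * ka_junc * (s1j - s2j) / s3j \
        / (1.0 + KSAT_NCX * ev_num1)
    s1sl = ev_nu * nasl ** 3 * CAO
    s2sl = ev_num1 * NAO ** 3 * casl
    s3sl = KM_CAI * NAO ** 3 * (1.0 + (nasl / KM_NAI) ** 3) \
        + KM_NAO ** 3 * casl * (1.0 + casl / KM_CAI) \
        + KM_CAO * nasl ** 3 + nasl ** 3 * CAO + NAO ** 3 * casl
    i_ncx_sl = FSL * p[P_IBARNCX] * ka_sl * (s1sl - s2sl) / s3sl \
        / (1.0 + KSAT_NCX * ev_num1)
    if clamp_kind == CLAMP_CURRENT:
        if clamp_code == 4:
            i_ncx_junc = clamp_val
        elif clamp_code == 5:
            i_ncx_sl = clamp_val

    # ---- sarcolemmal Ca2+ pump and background --------------------------
    i_pca_junc = FJUNC * IBAR_SLCAP * caj ** 1.6 / (KM_PCA ** 1.6 + caj ** 1.6)
    i_pca_sl = FSL * IBAR_SLCAP * casl ** 1.6 / (KM_PCA ** 1.6 + casl ** 1.6)
    i_cabk_junc = FJUNC * GCAB * (vm - eca_junc)
    i_cabk_sl = FSL * GCAB * (vm - eca_sl)
    if p[P_BLOCK_SLCA] > 0.5:
        # closed-cell Ca2+ mode: every sarcolemmal Ca2+ pathway silenced
        i_cal_junc = 0.0
        i_cal_sl = 0.0
        i_ncx_junc = 0.0
        i_ncx_sl = 0.0
        i_pca_junc = 0.0
        i_pca_sl = 0.0
        i_cabk_junc = 0.0
        i_cabk_sl = 0.0

    # ---- SR fluxes ------------------------------------------------------
    casr = y[I_CASR]          # JSR concentration in the Sato-Bers layout
    cansr = y[I_CSQNB]        # NSR concentration (Sato-Bers only)
    v_sr = p[P_VSR_FRAC] * V_CELL
    j_tr = 0.0
    if not sato:
        kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (p[P_EC50SR] / casr) ** 2.5)
        ko_srca = p[P_KOCA] / kcasr
        ki_srca = p[P_KICA] * kcasr
        ri = 1.0 - y[I_RYRR] - y[I_RYRO] - y[I_RYRI]
        dydt[I_RYRR] = (p[P_KIM] * ri - ki_srca * caj * y[I_RYRR]) \
            - (ko_srca * caj ** 2 * y[I_RYRR] - p[P_KOM] * y[I_RYRO])
        dydt[I_RYRO] = (ko_srca * caj ** 2 * y[I_RYRR] - p[P_KOM] * y[I_RYRO]) \
            - (ki_srca * caj * y[I_RYRO] - p[P_KIM] * y[I_RYRI])
        dydt[I_RYRI] = (ki_srca * caj * y[I_RYRO] - p[P_KIM] * y[I_RYRI]) \
            - (p[P_KOM] * y[I_RYRI] - ko_srca * caj ** 2 * ri)
        j_srcarel = p[P_KS] * y[I_RYRO] * (casr - caj)
        serca_src = casr
        rel_vol_frac = v_sr
    else:
        # CSQN-regulated RyR: opening rate switches between the
        # CSQN-unbound (K_u) and CSQN-bound (K_b) values; b relaxes toward
        # the Ca-free CSQN fraction with fast binding / slow unbinding.
        b = y[I_RYRI]
        # quadratic Ca2+-induced-Ca2+-release trigger (unsaturated over the
        # physiological cleft range); SB_KCP is the reference concentration
        trig = (caj / SB_KCP) ** 2
        a_open = trig * ((1.0 - b) * p[P_KU] + b * p[P_KB])
        a_close = p[P_K34]
        xinf[I_RYRO] = a_open / (a_open + a_close)
        xtau[I_RYRO] = 1.0 / (a_open + a_close)
        dydt[I_RYRO] = a_open * (1.0 - y[I_RYRO]) - a_close * y[I_RYRO]
        binf = p[P_KD_CSQN] / (p[P_KD_CSQN] + casr)
        taub = p[P_TAUB] if binf > b else p[P_TAUU]
        xinf[I_RYRI] = binf
        xtau[I_RYRI] = taub
        dydt[I_RYRI] = (binf - b) / taub
        dydt[I_RYRR] = 0.0
        j_srcarel = p[P_KS] * y[I_RYRO] * (casr - caj)
        j_tr = (cansr - casr) / p[P_TAUTR]
        serca_src = cansr
        rel_vol_frac = p[P_VJSR_FRAC] * V_CELL

    fwd = (cai / p[P_KMF]) ** HILL_SERCA
    rev = (serca_src / KMR_SERCA) ** HILL_SERCA
    j_serca = p[P_VMAXSRCAP] * (fwd - rev) / (1.0 + fwd + rev)
    if not sato:
        j_srleak = p[P_KLEAK] * (casr - caj)
    else:
        j_srleak = p[P_KLEAK] * (cansr - caj)
    if clamp_kind == CLAMP_CURRENT:
        if clamp_code == 1:
            j_srcarel = clamp_val
        elif clamp_code == 2:
            j_serca = clamp_val
        elif clamp_code == 3:
            j_srleak = clamp_val

    # ---- buffers --------------------------------------------------------
    a = KON_NA * naj * BMAX_NAJ
    bb = KON_NA * naj + KOFF_NA
    xinf[I_NABJ] = a / bb
    xtau[I_NABJ] = 1.0 / bb
    d_nabj = KON_NA * naj * (BMAX_NAJ - y[I_NABJ]) - KOFF_NA * y[I_NABJ]
    dydt[I_NABJ] = d_nabj
    a = KON_NA * nasl * BMAX_NASL
    bb = KON_NA * nasl + KOFF_NA
    xinf[I_NABSL] = a / bb
    xtau[I_NABSL] = 1.0 / bb
    d_nabsl = KON_NA * nasl * (BMAX_NASL - y[I_NABSL]) - KOFF_NA * y[I_NABSL]
    dydt[I_NABSL] = d_nabsl

    d_tncl = KON_TNCL * cai * (BMAX_TNCLOW - y[I_TNCL]) - KOFF_TNCL * y[I_TNCL]
    xinf[I_TNCL] = KON_TNCL * cai * BMAX_TNCLOW / (KON_TNCL * cai + KOFF_TNCL)
    xtau[I_TNCL] = 1.0 / (KON_TNCL * cai + KOFF_TNCL)
    cap_hc = BMAX_TNCHIGH - y[I_TNCHM]
    d_tnchc = KON_TNCHCA * cai * (BMAX_TNCHIGH - y[I_TNCHC] - y[I_TNCHM]) \
        - KOFF_TNCHCA * y[I_TNCHC]
    xinf[I_TNCHC] = KON_TNCHCA * cai * cap_hc / (KON_TNCHCA * cai + KOFF_TNCHCA)
    xtau[I_TNCHC] = 1.0 / (KON_TNCHCA * cai + KOFF_TNCHCA)
    cap_hm = BMAX_TNCHIGH - y[I_TNCHC]
    d_tnchm = KON_TNCHMG * MGI * (BMAX_TNCHIGH - y[I_TNCHC] - y[I_TNCHM]) \
        - KOFF_TNCHMG * y[I_TNCHM]
    xinf[I_TNCHM] = KON_TNCHMG * MGI * cap_hm / (KON_TNCHMG * MGI + KOFF_TNCHMG)
    xtau[I_TNCHM] = 1.0 / (KON_TNCHMG * MGI + KOFF_TNCHMG)
    d_cam = KON_CAM * cai * (BMAX_CAM - y[I_CAM]) - KOFF_CAM * y[I_CAM]
    xinf[I_CAM] = KON_CAM * cai * BMAX_CAM / (KON_CAM * cai + KOFF_CAM)
    xtau[I_CAM] = 1.0 / (KON_CAM * cai + KOFF_CAM)
    cap_mc = BMAX_MYOSIN - y[I_MYOM]
    d_myoc = KON_MYOCA * cai * (BMAX_MYOSIN - y[I_MYOC] - y[I_MYOM]) \
        - KOFF_MYOCA * y[I_MYOC]
    xinf[I_MYOC] = KON_MYOCA * cai * cap_mc / (KON_MYOCA * cai + KOFF_MYOCA)
    xtau[I_MYOC] = 1.0 / (KON_MYOCA * cai + KOFF_MYOCA)
    cap_mm = BMAX_MYOSIN - y[I_MYOC]
    d_myom = KON_MYOMG * MGI * (BMAX_MYOSIN - y[I_MYOC] - y[I_MYOM]) \
        - KOFF_MYOMG * y[I_MYOM]
    xinf[I_MYOM] = KON_MYOMG * MGI * cap_mm / (KON_MYOMG * MGI + KOFF_MYOMG)
    xtau[I_MYOM] = 1.0 / (KON_MYOMG * MGI + KOFF_MYOMG)
    d_srb = KON_SR * cai * (BMAX_SR - y[I_SRB]) - KOFF_SR * y[I_SRB]
    xinf[I_SRB] = KON_SR * cai * BMAX_SR / (KON_SR * cai + KOFF_SR)
    xtau[I_SRB] = 1.0 / (KON_SR * cai + KOFF_SR)
    dydt[I_TNCL] = d_tncl
    dydt[I_TNCHC] = d_tnchc
    dydt[I_TNCHM] = d_tnchm
    dydt[I_CAM] = d_cam
    dydt[I_MYOC] = d_myoc
    dydt[I_MYOM] = d_myom
    dydt[I_SRB] = d_srb
    j_cab_cytosol = d_tncl + d_tnchc + d_cam + d_myoc + d_srb

    # Membrane (junctional / sub-sarcolemmal) Ca2+ buffers.  At the 20 µs
    # explicit step these sites are numerically stiff (buffer slope times
    # response fraction exceeds one), so the default treats them with the
    # rapid-buffering (fast-equilibrium) approximation: states track their
    # equilibrium and the compartment derivative is scaled by beta(ca).
    fastbuf = p[P_FASTBUF] > 0.5
    kd_sll = KOFF_SLL / KON_SLL
    kd_slh = KOFF_SLH / KON_SLH
    if fastbuf:
        xinf[I_SLLJ] = BMAX_SLLJ * caj / (kd_sll + caj)
        xinf[I_SLHJ] = BMAX_SLHJ * caj / (kd_slh + caj)
        xinf[I_SLLSL] = BMAX_SLLSL * casl / (kd_sll + casl)
        xinf[I_SLHSL] = BMAX_SLHSL * casl / (kd_slh + casl)
        xtau[I_SLLJ] = -1.0
        xtau[I_SLHJ] = -1.0
        xtau[I_SLLSL] = -1.0
        xtau[I_SLHSL] = -1.0
        dydt[I_SLLJ] = 0.0
        dydt[I_SLHJ] = 0.0
        dydt[I_SLLSL] = 0.0
        dydt[I_SLHSL] = 0.0
        j_cab_junc = 0.0
        j_cab_sl = 0.0
        beta_j = 1.0 / (1.0 + BMAX_SLLJ * kd_sll / (kd_sll + caj) ** 2
                        + BMAX_SLHJ * kd_slh / (kd_slh + caj) ** 2)
        beta_sl = 1.0 / (1.0 + BMAX_SLLSL * kd_sll / (kd_sll + casl) ** 2
                         + BMAX_SLHSL * kd_slh / (kd_slh + casl) ** 2)
    else:
        d_sllj = KON_SLL * caj * (BMAX_SLLJ - y[I_SLLJ]) - KOFF_SLL * y[I_SLLJ]
        xinf[I_SLLJ] = KON_SLL * caj * BMAX_SLLJ / (KON_SLL * caj + KOFF_SLL)
        xtau[I_SLLJ] = 1.0 / (KON_SLL * caj + KOFF_SLL)
        d_sllsl = KON_SLL * casl * (BMAX_SLLSL - y[I_SLLSL]) \
            - KOFF_SLL * y[I_SLLSL]
        xinf[I_SLLSL] = KON_SLL * casl * BMAX_SLLSL / (KON_SLL * casl + KOFF_SLL)
        xtau[I_SLLSL] = 1.0 / (KON_SLL * casl + KOFF_SLL)
        d_slhj = KON_SLH * caj * (BMAX_SLHJ - y[I_SLHJ]) - KOFF_SLH * y[I_SLHJ]
        xinf[I_SLHJ] = KON_SLH * caj * BMAX_SLHJ / (KON_SLH * caj + KOFF_SLH)
        xtau[I_SLHJ] = 1.0 / (KON_SLH * caj + KOFF_SLH)
        d_slhsl = KON_SLH * casl * (BMAX_SLHSL - y[I_SLHSL]) \
            - KOFF_SLH * y[I_SLHSL]
        xinf[I_SLHSL] = KON_SLH * casl * BMAX_SLHSL / (KON_SLH * casl + KOFF_SLH)
        xtau[I_SLHSL] = 1.0 / (KON_SLH * casl + KOFF_SLH)
        dydt[I_SLLJ] = d_sllj
        dydt[I_SLLSL] = d_sllsl
        dydt[I_SLHJ] = d_slhj
        dydt[I_SLHSL] = d_slhsl
        j_cab_junc = d_sllj + d_slhj
        j_cab_sl = d_sllsl + d_slhsl
        beta_j = 1.0
        beta_sl = 1.0
    if sato or fastbuf:
        dydt[I_CSQNB] = 0.0
        xinf[I_CSQNB] = y[I_CSQNB]
        xtau[I_CSQNB] = 1e12
        d_csqn = 0.0
    else:
        d_csqn = KON_CSQN * casr * (p[P_BMAX_CSQN] - y[I_CSQNB]) \
            - KOFF_CSQN * y[I_CSQNB]
        xinf[I_CSQNB] = KON_CSQN * casr * p[P_BMAX_CSQN] \
            / (KON_CSQN * casr + KOFF_CSQN)
        xtau[I_CSQNB] = 1.0 / (KON_CSQN * casr + KOFF_CSQN)
        dydt[I_CSQNB] = d_csqn

    # ---- concentration ODEs --------------------------------------------
    i_na_tot_junc = i_na_junc + i_nabk_junc + 3.0 * i_ncx_junc \
        + 3.0 * i_nak_junc + i_cana_junc + i_nal_junc
    i_na_tot_sl = i_na_sl + i_nabk_sl + 3.0 * i_ncx_sl \
        + 3.0 * i_nak_sl + i_cana_sl + i_nal_sl
    dydt[I_NAJ] = -i_na_tot_junc * CMEM / (V_JUNC * FARADAY) \
        + J_NA_JUNCSL / V_JUNC * (nasl - naj) - d_nabj
    dydt[I_NASL] = -i_na_tot_sl * CMEM / (V_SL * FARADAY) \
        + J_NA_JUNCSL / V_SL * (naj - nasl) \
        + J_NA_SLMYO / V_SL * (nai - nasl) - d_nabsl
    dydt[I_NAI] = J_NA_SLMYO / V_MYO * (nasl - nai)
    dydt[I_KI] = 0.0

    i_ca_tot_junc = i_cal_junc + i_cabk_junc + i_pca_junc - 2.0 * i_ncx_junc
    i_ca_tot_sl = i_cal_sl + i_cabk_sl + i_pca_sl - 2.0 * i_ncx_sl
    if not sato:
        dydt[I_CAJ] = beta_j * (
            -i_ca_tot_junc * CMEM / (V_JUNC * 2.0 * FARADAY)
            + J_CA_JUNCSL / V_JUNC * (casl - caj) - j_cab_junc
            + j_srcarel * v_sr / V_JUNC + j_srleak * V_MYO / V_JUNC)
        if fastbuf:
            beta_sr = 1.0 / (1.0 + p[P_BMAX_CSQN] * p[P_KD_CSQN]
                             / (p[P_KD_CSQN] + casr) ** 2)
            dydt[I_CASR] = beta_sr * (j_serca - j_srleak * V_MYO / v_sr
                                      - j_srcarel)
        else:
            dydt[I_CASR] = j_serca - j_srleak * V_MYO / v_sr - j_srcarel \
                - d_csqn
        dydt[I_CAI] = -j_serca * v_sr / V_MYO - j_cab_cytosol \
            + J_CA_SLMYO / V_MYO * (casl - cai)
    else:
        v_jsr = p[P_VJSR_FRAC] * V_CELL
        v_nsr = p[P_VNSR_FRAC] * V_CELL
        dydt[I_CAJ] = beta_j * (
            -i_ca_tot_junc * CMEM / (V_JUNC * 2.0 * FARADAY)
            + J_CA_JUNCSL / V_JUNC * (casl - caj) - j_cab_junc
            + j_srcarel * v_jsr / V_JUNC + j_srleak * V_MYO / V_JUNC)
        beta_jsr = 1.0 / (1.0 + p[P_BMAX_CSQN] * p[P_KD_CSQN]
                          / (p[P_KD_CSQN] + casr) ** 2)
        dydt[I_CASR] = beta_jsr * (j_tr - j_srcarel)
        dydt[I_CSQNB] = j_serca - j_tr * v_jsr / v_nsr \
            - j_srleak * V_MYO / v_nsr
        xinf[I_CSQNB] = 0.0
        xtau[I_CSQNB] = 0.0
        dydt[I_CAI] = -j_serca * v_nsr / V_MYO - j_cab_cytosol \
            + J_CA_SLMYO / V_MYO * (casl - cai)
    dydt[I_CASL] = beta_sl * (
        -i_ca_tot_sl * CMEM / (V_SL * 2.0 * FARADAY)
        + J_CA_JUNCSL / V_SL * (caj - casl)
        + J_CA_SLMYO / V_SL * (cai - casl) - j_cab_sl)

    i_na_tot = i_na_tot_junc + i_na_tot_sl
    i_cl_tot = i_clca + i_clbk
    i_ca_tot = i_ca_tot_junc + i_ca_tot_sl
    i_k_tot = i_kr + i_ks + i_k1 + i_kp + i_to + i_kur \
        - 2.0 * (i_nak_junc + i_nak_sl) + i_cak
    i_tot = i_na_tot + i_cl_tot + i_ca_tot + i_k_tot
    dydt[I_VM] = -(i_tot - i_app)

    cur[C_INA] = i_na_junc + i_na_sl
    cur[C_INAL] = i_nal_junc + i_nal_sl
    cur[C_INABK] = i_nabk_junc + i_nabk_sl
    cur[C_INAK] = i_nak_junc + i_nak_sl
    cur[C_IKR] = i_kr
    cur[C_IKS] = i_ks
    cur[C_IKP] = i_kp
    cur[C_ITO] = i_to
    cur[C_IKUR] = i_kur
    cur[C_IK1] = i_k1
    cur[C_ICLCA] = i_clca
    cur[C_ICLBK] = i_clbk
    cur[C_ICALJ] = i_cal_junc
    cur[C_ICALSL] = i_cal_sl
    cur[C_ICAK] = i_cak
    cur[C_ICANA] = i_cana_junc + i_cana_sl
    cur[C_INCXJ] = i_ncx_junc
    cur[C_INCXSL] = i_ncx_sl
    cur[C_IPCA] = i_pca_junc + i_pca_sl
    cur[C_ICABK] = i_cabk_junc + i_cabk_sl
    cur[C_JREL] = j_srcarel
    cur[C_JSERCA] = j_serca
    cur[C_JLEAK] = j_srleak
    cur[C_ITOT] = i_tot
    cur[C_JTR] = j_tr

    if clamp_kind == CLAMP_STATE:
        dydt[clamp_code] = 0.0


# states updated exponentially (gates + linear buffers); compartment feedback
# pairs (buffer state -> ion state) used for mass-consistent stepping.
_EXP_STATES = np.array(
    [I_M, I_H, I_J, I_D, I_F, I_FCABJ, I_FCABSL, I_XTOF, I_YTOF, I_XKUR,
     I_YKUR, I_XKR, I_XKS, I_ML, I_HL,
     I_NABJ, I_NABSL, I_TNCL, I_TNCHC, I_TNCHM, I_CAM, I_MYOC, I_MYOM,
     I_SRB, I_SLLJ, I_SLLSL, I_SLHJ, I_SLHSL, I_CSQNB], dtype=np.int64)
# ion slot each exponential state feeds back on (-1: none, Mg buffers/gates)
_EXP_FEEDBACK = np.array(
    [-1] * 15
    + [I_NAJ, I_NASL, I_CAI, I_CAI, -1, I_CAI, I_CAI, -1,
       I_CAI, I_CAJ, I_CASL, I_CAJ, I_CASL, I_CASR], dtype=np.int64)
# Euler-updated states
_FE_STATES = np.array(
    [I_VM, I_RYRR, I_RYRO, I_RYRI, I_CASR, I_NAJ, I_NASL, I_NAI,
     I_KI, I_CAJ, I_CASL, I_CAI, I_CSQNB], dtype=np.int64)


@njit(cache=True, fastmath=True)
def _apply_update(y, p, dt, dydt, xinf, xtau):
    """Apply one Rush-Larsen / forward-Euler update of width dt (in place)."""
    sato = p[P_RYRFORM] > 0.5
    # forward-Euler block
    for k in range(_FE_STATES.shape[0]):
        i = _FE_STATES[k]
        if sato and (i == I_RYRO or i == I_RYRI):
            continue  # handled exponentially below
        if i == I_CSQNB and not sato:
            continue  # kinetic CSQN belongs to the exponential block
        y[i] = y[i] + dt * dydt[i]
    # exponential block with mass-consistent feedback on the ion pools
    for k in range(_EXP_STATES.shape[0]):
        i = _EXP_STATES[k]
        if i == I_CSQNB and (sato or p[P_FASTBUF] > 0.5):
            continue
        if xtau[i] < 0.0:
            # fast-equilibrium buffer: track equilibrium, no mass exchange
            y[i] = xinf[i]
            continue
        old = y[i]
        new = xinf[i] + (old - xinf[i]) * np.exp(-dt / xtau[i])
        y[i] = new
        fb = _EXP_FEEDBACK[k]
        if fb >= 0:
            # replace the Euler buffer-flux estimate by the applied increment
            y[fb] += dt * dydt[i] - (new - old)
    if sato:
        y[I_RYRO] = xinf[I_RYRO] + (y[I_RYRO] - xinf[I_RYRO]) \
            * np.exp(-dt / xtau[I_RYRO])
        y[I_RYRI] = xinf[I_RYRI] + (y[I_RYRI] - xinf[I_RYRI]) \
            * np.exp(-dt / xtau[I_RYRI])


@njit(cache=True, fastmath=True)
def step_cell(y, p, dt, i_app, clamp_kind, clamp_code, clamp_idx, clamp_val,
              dydt, cur, xinf, xtau, ab2):
    """Advance the state by one step of dt (in place).

    Steep Ca2+-induced-Ca2+-release transients can move junctional [Ca2+]
    by more than its own magnitude within 20 µs; such steps are subdivided
    (relative-increment guard on ca_j and ca_sr) so the explicit update
    never overshoots the cleft.

    The membrane potential is advanced with a two-step Adams-Bashforth
    update (``ab2`` carries [previous dV/dt, history-valid flag]); the
    first-order V_m truncation error otherwise accumulates to >1 ms of APD
    at the 20 µs operating step.  History is reset across substepped
    (release-transient) steps and stimulus edges.
    """
    if clamp_kind == CLAMP_STATE:
        y[clamp_idx] = clamp_val
    ccode = clamp_code if clamp_kind == CLAMP_CURRENT else clamp_idx
    eval_cell(y, p, i_app, clamp_kind, ccode, clamp_val,
              dydt, cur, xinf, xtau)
    lim_j = 0.25 * y[I_CAJ] + 1e-4
    lim_sr = 0.25 * y[I_CASR] + 1e-4
    need = max(np.abs(dydt[I_CAJ]) * dt / lim_j,
               np.abs(dydt[I_CASR]) * dt / lim_sr)
    n_sub = 1
    if need > 1.0:
        n_sub = int(min(np.ceil(need), 64.0))
    f0_vm = dydt[I_VM]
    h = dt / n_sub
    _apply_update(y, p, h, dydt, xinf, xtau)
    if n_sub == 1:
        if ab2[1] > 0.5:
            y[I_VM] += 0.5 * dt * (f0_vm - ab2[0])
        ab2[0] = f0_vm
        ab2[1] = 1.0
    else:
        ab2[1] = 0.0
        for _ in range(n_sub - 1):
            if clamp_kind == CLAMP_STATE:
                y[clamp_idx] = clamp_val
            eval_cell(y, p, i_app, clamp_kind, ccode, clamp_val,
                      dydt, cur, xinf, xtau)
            _apply_update(y, p, h, dydt, xinf, xtau)
    if clamp_kind == CLAMP_STATE:
        y[clamp_idx] = clamp_val


@njit(cache=True)
def run_paced(y, p, dt, cl, n_beats, stim_amp, stim_dur,
              clamp_kind, clamp_code, clamp_idx, clamp_wave,
              rec_state, rec_cur, stride, out_state, out_cur):
    """Pace ``n_beats`` beats of cycle length ``cl`` (stimulus at each beat
    start), recording selected states/currents every ``stride`` steps.

    Returns the step index of the first non-finite membrane potential, or -1
    on success.  ``clamp_wave`` holds one cycle of the clamp waveform sampled
    at dt (ignored when clamp_kind == 0).
    """
    dydt = np.zeros(N_STATE)
    cur = np.zeros(N_CURRENT)
    xinf = np.zeros(N_STATE)
    xtau = np.ones(N_STATE)
    ab2 = np.zeros(2)
    n_per_beat = int(round(cl / dt))
    n_stim = int(round(stim_dur / dt))
    isample = 0
    step = 0
    for b in range(n_beats):
        for k in range(n_per_beat):
            cval = clamp_wave[k % clamp_wave.shape[0]] \
                if clamp_kind != CLAMP_NONE else 0.0
            if step % stride == 0 and isample < out_state.shape[1]:
                if clamp_kind == CLAMP_STATE:
                    y[clamp_idx] = cval
                for r in range(rec_state.shape[0]):
                    out_state[r, isample] = y[rec_state[r]]
                if rec_cur.shape[0] > 0:
                    eval_cell(y, p, 0.0, clamp_kind,
                              clamp_code if clamp_kind == CLAMP_CURRENT
                              else clamp_idx,
                              cval, dydt, cur, xinf, xtau)
                    for r in range(rec_cur.shape[0]):
                        out_cur[r, isample] = cur[rec_cur[r]]
                isample += 1
            i_app = stim_amp if k < n_stim else 0.0
            step_cell(y, p, dt, i_app, clamp_kind, clamp_code, clamp_idx,
                      cval, dydt, cur, xinf, xtau, ab2)
            if y[I_VM] != y[I_VM]:
                return step
            step += 1
    return -1


@njit(cache=True)
def run_cable(Y, p, dt, cl, n_beats, stim_amp, stim_dur, n_stim_nodes,
              lam, stride, rec_nodes, out_vm):
    """Operator-split monodomain cable: per-node ionic step then explicit
    diffusion with no-flux ends.  ``lam = D*dt/dx^2``.  ``out_vm`` has shape
    (len(rec_nodes), n_samples).  Returns -1 on success or failing step
    index."""
    n_nodes = Y.shape[0]
    dydt = np.zeros(N_STATE)
    cur = np.zeros(N_CURRENT)
    xinf = np.zeros(N_STATE)
    xtau = np.ones(N_STATE)
    ab2 = np.zeros((n_nodes, 2))
    vnew = np.zeros(n_nodes)
    n_per_beat = int(round(cl / dt))
    n_stim = int(round(stim_dur / dt))
    isample = 0
    step = 0
    for b in range(n_beats):
        for k in range(n_per_beat):
            if step % stride == 0 and isample < out_vm.shape[1]:
                for r in range(rec_nodes.shape[0]):
                    out_vm[r, isample] = Y[rec_nodes[r], I_VM]
                isample += 1
            stim_on = k < n_stim
            for n in range(n_nodes):
                i_app = stim_amp if (stim_on and n < n_stim_nodes) else 0.0
                step_cell(Y[n], p, dt, i_app, CLAMP_NONE, 0, 0, 0.0,
                          dydt, cur, xinf, xtau, ab2[n])
            # diffusion on vm, no-flux boundaries
            for n in range(n_nodes):
                vl = Y[n - 1, I_VM] if n > 0 else Y[1, I_VM]
                vr = Y[n + 1, I_VM] if n < n_nodes - 1 else Y[n_nodes - 2, I_VM]
                vnew[n] = Y[n, I_VM] + lam * (vl - 2.0 * Y[n, I_VM] + vr)
            for n in range(n_nodes):
                Y[n, I_VM] = vnew[n]
                if vnew[n] != vnew[n]:
                    return step
            step += 1
    return -1
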
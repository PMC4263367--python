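# Methods

## The model

`atrialternans` simulates the electrophysiology of a human atrial myocyte
with the Grandi–Pandit–Voigt (GPV) 2011 human atrial action-potential model,
carrying two modifications (we call the result the GPVm model):

1. the fast Na⁺ current gating (m, h, j) uses the Luo–Rudy dynamic (LRd)
   rate functions, which propagate robustly in tissue at fast rates where
   the original formulation fails; the maximal conductance g_Na remains a
   model parameter;
2. the stiff membrane-site Ca²⁺ buffers (the low- and high-affinity
   sarcolemmal/junctional sites) and calsequestrin are treated with the
   rapid-buffering (fast-equilibrium) approximation by default (see
   *Numerics*).

The cell has four Ca²⁺ spaces — junctional cleft, sub-sarcolemmal space,
bulk cytosol, and SR — with the GPV volumes, diffusional couplings,
buffers, membrane currents (I_Na, I_NaL, I_CaL, I_to, I_Kur, I_Kr, I_Ks,
I_K1, I_Kp, Cl⁻ currents, NCX, Na/K pump, sarcolemmal Ca²⁺ pump and
backgrounds), SERCA uptake, SR leak, and a four-state Markov ryanodine
receptor (R, O, I, and the closed-inactivated state) whose opening and
inactivation rates are modulated by luminal SR Ca²⁺:

    kCaSR  = MaxSR − (MaxSR − MinSR) / (1 + (ec50SR/[Ca]_SR)^2.5)
    k_open = ko_Ca/kCaSR · [Ca]_j²       k_inact = ki_Ca·kCaSR · [Ca]_j
    J_SRCarel = k_s · O · ([Ca]_SR − [Ca]_j)

Two disease variants are built in. *Chronic AF* (cAF) remodeling
multiplies exactly ten parameters of the control model: g_Na ×0.9,
g_NaL 0→0.0025 mS/µF, g_CaL ×0.5, g_to ×0.3, g_Kur ×0.5, g_K1 ×2, g_Ks ×2,
Ibar_NCX ×1.4, ko_Ca ×3 and k_leak ×1.25.  The *right atrium* differs from
the reference left atrium by a larger I_Kur (g_Kur ×1.2).  User scale
factors compose multiplicatively on top of the variant; the
alternans-prone cell studied throughout is cAF with `ki_Ca: 0.5`.

One deliberate baseline departure from the ventricular constant set: the
SERCA forward affinity K_mf is 0.615 µM (2.5× the ventricular value), the
atrial adjustment of the source model; it produces the characteristically
high atrial diastolic [Ca²⁺]_i (≈0.2 µM in control here) and slower
cytosolic Ca²⁺ decline.

An alternative SR-release formulation replaces the RyR Markov scheme with a
calsequestrin(CSQN)-regulated channel and splits the SR into junctional
(JSR) and network (NSR) compartments.  Release terminates through CSQN
binding to the RyR as luminal Ca²⁺ falls rather than through
Ca²⁺-dependent inactivation: the RyR opening rate switches between a
CSQN-unbound value K_u = 15 ms⁻¹ and a CSQN-bound value K_b = 0.015 ms⁻¹
according to a bound fraction that relaxes toward the Ca-free CSQN
fraction K_C/(K_C+[Ca]_JSR) with fast binding (τ_b = 0.164 ms) and slow
unbinding (τ_u = 312 ms); the JSR refills from the NSR with τ_tr = 5 ms.
The CICR trigger multiplying both opening rates is quadratic in cleft
Ca²⁺, ([Ca]_j / 0.2 mM)²; the closing rate k_34 (baseline 1 ms⁻¹, the
analogue of ki_Ca) is scalable.  The trigger reference, k_34 baseline and
the mean-field reduction of the four-state scheme are this package's own
choices — the published description fixes only the constants listed above —
so only structural properties of this variant are asserted by the tests
(first-order JSR refill, JSR-gradient release, CSQN occupancy bounds).
Beat-to-beat release in this variant carries a long CSQN-unbinding memory;
consistent with the source literature it oscillates at slow pacing and its
release–load relation is poorly conditioned, which is why the slope assay
excludes each run's first post-perturbation beat here.

## Protocols

*Clinical ramp.* 20 beats at 750-ms CL, then 74 beats per CL from 500 ms in
50-ms steps to 300 ms and in 10-ms steps below (analysis restricted to
CL ≥ 300 ms).  Per CL the last 11 beats give: APD90 (time from maximal
upstroke velocity to 90% repolarization of the phase-II amplitude),
alternans magnitude (mean |ΔAPD| over the last 10 beat pairs), mean APD
(last 10 beats), and ANM = magnitude/mean APD.  Alternans onset is the
longest CL with ANM > 0.05.  The phase-II amplitude is defined
operationally as (max V_m within 5–100 ms after the upstroke) − (pre-
stimulus diastolic V_m), excluding the phase-0/1 spike; an analysis window
this wide makes APD90 insensitive to the exact bounds for atrial AP shapes.

*Variable clamps.* At a CL showing alternans, the period-2 steady state is
recorded and one model variable (any state except buffer concentrations, or
one of the SR fluxes / NCX / L-type components) is clamped to its even- or
odd-beat waveform for 50 beats; the percent change of APD- and
CaT-alternans magnitudes against the unclamped baseline is reported.  CaT
amplitude is peak [Ca²⁺]_i minus the preceding diastolic minimum.  The
*even* beat is defined as the smaller-CaT (short) beat — beat-index parity
at a new CL is arbitrary, so both parities are always reported.

*AP clamp.* V_m is clamped to the analytic atrial AP surrogate
V(t) = V_rest + (V_max − V_rest)·√(1 − (t/APD)²) for t < APD and V_rest
thereafter, with V_max = 10 mV, V_rest = −75 mV, APD = 200 ms, CL from 200
to 700 ms.  This removes bidirectional V_m–Ca²⁺ coupling so Ca²⁺-cycling
stability can be probed in isolation.

*Release-slope assay.* From the AP-clamped steady state, [Ca²⁺]_SR is
perturbed over a spread of factors at a beat start and (pre-release total
SR load, total release) pairs are recorded over the following beats; the
least-squares slope of release on load is the SR Ca²⁺ release slope m.
Loads and releases are volume-weighted to cytosol and the SR load includes
CSQN-bound Ca²⁺.

## Iterated-map analysis

Under AP clamp the beat-to-beat Ca²⁺ dynamics reduce to a two-variable map
in pre-release SR load l_n and total cell Ca²⁺ T_n:

    l_{n+1} = l_n − r(l_n) + U_n
    T_{n+1} = T_n + I_n − E_n

Linearizing about the fixed point with release slope m = dr/dl, uptake
factor u (response of per-beat SERCA uptake to the cytosolic Ca²⁺
deviation δr + δd, d = T − l) and efflux factor κ (same response of net
sarcolemmal efflux) gives the Jacobian
[[(1−m)(1−u), u], [κ(1−m), 1−κ]], whose period-doubling condition
(eigenvalue −1) yields the alternans threshold

    m_thr(u, κ) = 1 + (2 − κ) / (2 − 2u − κ),   valid for u < 1 − κ/2,

with stability iff m < m_thr.  The threshold rises with κ — Ca²⁺ extrusion
is protective, the opposite sign to map analyses in which efflux drives
alternans — and all κ-curves converge to m_thr = 2 as u → 0, so efflux
matters little when uptake efficiency is poor.  These two properties are
asserted as unit tests.

Parameters are estimated exactly as the protocol prescribes: at the
AP-clamped steady state [Ca²⁺]_SR is perturbed by ±1% at the start of an
even and of an odd beat (four runs) and per-beat load, release, uptake and
sarcolemmal efflux are recorded for 10 beats per run (40 beats pooled; the
CSQN-regulated variant drops each run's first beat, 36).  Deviations are
taken against a parallel unperturbed run, which cancels the slow residual
drift of the reference orbit; m, u and κ are least-squares slopes with R²
recorded and a quality flag below R² = 0.95.  The per-beat ledger obeys
Δload = uptake − release − leak to the quadrature error of the recording
grid (sub-1e-3 mM per beat at the 0.1-ms sampling used).

## Tissue fiber

The 0.33 × 0.33 × 9.9 mm³ preparation is reduced to a 1-D monodomain cable
(its cross-section is far below the space constant): 0.1-mm node spacing by
default, no-flux ends, stimulus applied as transmembrane current to the
proximal 0.33 mm, recording electrode 0.5 mm from the distal end.  The
diffusion coefficient is D = σ/(β·C_m) with the cell's surface-to-volume
ratio β derived from its capacitance and geometry; the bulk conductivity σ
is tuned by bisection so the control fiber conducts at 0.62 m/s (CV from a
linear fit of activation time — maximal dV/dt — against distance over the
central half of the fiber).  Operator splitting advances each node's ionic
state and then the explicit diffusion update; the diffusion number
D·Δt/Δx² is guarded below 0.5.

## Numerics

Fixed 20 µs step throughout.  Hodgkin–Huxley gates use the Rush–Larsen
exponential update.  Buffer ODEs are linear in the bound concentration and
are also advanced exponentially, with the applied increment substituted
into the paired ion-pool update so Ca²⁺/Na⁺ mass exchange is exact; in a
closed-cell test (all sarcolemmal Ca²⁺ pathways silenced) total cell Ca²⁺
is conserved to 1e-9 relative over a beat.  The membrane-site buffers are
numerically stiff at 20 µs (buffer slope × per-step response exceeds
unity, which destabilizes the junctional cleft), so they and CSQN default
to the rapid-buffering approximation — switching to the explicit kinetic
form at a refined step changes V_m traces by < 1 mV pointwise, which the
suite verifies.  V_m itself is advanced with a two-step Adams–Bashforth
update: with plain forward Euler the first-order V_m error accumulates to
≈1.6 ms of APD90 at the default step; with AB2 halving the step changes
APD90 by < 0.6 ms.  Steep CICR transients are handled by subdividing any
step whose junctional or SR Ca²⁺ increment would exceed 25% of the
current value (AB2 history is reset across such steps).  Steady states are
declared at a relative L∞ change below 1e-4 across a period-2 window,
excluding the Na⁺ pools, which creep for thousands of beats at a rate
irrelevant to Ca²⁺-cycling dynamics; period-2 orbits are distinguished
from drift by comparing consecutive-beat to alternate-beat state
differences.

The stimulus is not part of the published protocol: the default is twice
the diastolic threshold found by bisection for a 2-ms pulse, recorded in
run metadata; the test-suite and acceptance runs pin 12.5 A/F (cell) and
25 A/F (fiber), both supra-threshold, for determinism.

## Problem sizes used in the checked runs

The acceptance runs use the full single-cell protocols; the tissue ramp
runs on a 0.18-mm mesh (55 segments), which reproduces the 0.1-mm-mesh
onset CL exactly and its APD metrics within a fraction of a millisecond in
a quarter of the time.  CV tuning uses the full 0.1-mm mesh.  The
282-simulation sensitivity sweep and the 500-sample regression are
overnight-scale; the suite exercises them at reduced size (single-parameter
sweeps; the regression machinery against an analytic threshold surrogate
with known coefficients).

## What the synthetic protocols do and do not show

All inputs are generated by the model itself (there is no external data
path beyond re-analysis of recorded traces), so agreement with the source
study's numbers tests the fidelity of the model reconstruction and
protocol definitions, not properties of patient data.  The reconstruction
reproduces the study's tissue-level findings (alternans onset CL, mean APD
and magnitude at onset, the SR-load alternation pair, steady-state SR
contrasts, CSQN-bound occupancy behavior, and the qualitative clamp
taxonomy — SR-release variables abolish alternans, V_m does not).  Known
quantitative deviations, all traceable to source details unavailable in
the extracted supplement (exact AP-clamp waveform equation, the precise
fast-equilibrium buffer set, and the S1-Text normalization of u and κ):
the AP-clamped release slopes run ≈25–40% steeper than published
(2.4/3.9 vs 1.7/3.1), the iterated-map threshold crossing lands at 360 ms
rather than 390 ms (the map and direct simulation agree with *each other*
within one 10-ms step, as published), the even-beat V_m clamp reduces CaT
alternans by 26% rather than 62%, and the cAF conduction-velocity
reduction is 0.017 m/s rather than 0.03 m/s.

## Limitations

Single homogeneous fiber only — no 2-D/3-D anatomy, fibrosis or discordant
alternans; no subcellular Ca²⁺ sparks or t-tubule heterogeneity; signaling
(CaMKII/PKA) is represented only phenomenologically through the ki_Ca
scale factor; intracellular K⁺ is fixed and Na⁺ drifts slowly, as in the
source model; the CSQN-regulated release variant is a structural
reconstruction whose quantitative behavior is not pinned by published
constants.
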
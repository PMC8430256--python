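# Methods

## Overview

`cardioemd` simulates the excitation–contraction coupling of a single human
ventricular myocyte and asks which sarcolemmal conductances, when reduced,
prolong the electromechanical delay (EMD) — the time between the electrical
firing of the cell and the onset of its mechanical shortening. The pipeline
has four stages: (1) a paced electrophysiology (EP) simulation of a human
ventricular ionic model under per-channel conductance scaling, (2) a
myofilament contraction model driven one-way by the EP calcium transient,
(3) scalar biomarker extraction, and (4) a factorial population sweep whose
results are embedded into dimensional-stacking maps with an
axis-order optimization.

## Electrophysiology

The ionic model is the ten Tusscher–Panfilov human ventricular myocyte
model (epicardial parameter set by default; endo- and mid-myocardial
variants are selectable). It comprises 12 sarcolemmal currents, a
four-state Markov ryanodine receptor reduced to one tracked aggregate
R̄ = R + O with the algebraic open fraction
O = k1·Ca_SS²·R̄/(k3 + k1·Ca_SS²), and three calcium compartments
(cytosol, SR, diadic subspace) with rapid-equilibrium buffering solved
analytically per step. Ten currents (Na, CaL, to, Kr, Ks, K1, pK, pCa,
bNa, bCa) accept a dimensionless multiplier on their maximum
conductance/permeability; the NCX exchanger and the Na/K pump are never
scaled, and scaling never touches gating kinetics.

Integration is operator-split and fully deterministic: Rush–Larsen
exponential updates for the 12 Hodgkin–Huxley gates, explicit Euler for
V, the ion concentrations and R̄, at an internal step of 0.02 ms with
1 ms output sampling. Halving the step moves the normal-case APD90 by
well under 1 ms and peak Ca by < 0.1 %, so the scheme is converged at the
biomarker level. A non-finite state aborts the case and is recorded as a
diverged row in sweep output rather than raised.

### Pacing protocol and initial conditions

Every case starts from the model's 1-Hz paced steady-state values (the
initial conditions shipped with the curated model distribution) and is
paced with −52 pA/pF, 1 ms stimuli for 50 beats at BCL 600 ms; the run
then continues, without reset, for 50 further beats at BCL 1000 ms. The
final beat of each phase is the case's trace at that BCL. The sequential
(S1→S2-like) design matters quantitatively: it reproduces the normal-case
peak Ca_i of 1.247 μM (600 ms) and 0.889 μM (1000 ms) to better than 1 %,
whereas two independent runs from the published resting state
underestimate both by 7–14 % because 50 beats do not erase the slow Na⁺/K⁺
drift from rest. Since all 4^10 cases share the same starting state, the
pre-pacing washes out initial-condition sensitivity.

## Myofilament mechanics

The contraction model is the Rice-type lumped sarcomere: Ca binding to
high/low-affinity troponin sites; cooperative regulatory switching between
non-permissive (N) and permissive (P) states with
permtot = sqrt(1/(1 + (perm50/Trop_Regulatory)^n_perm)), perm50 = 0.5,
n_perm = 15, and the capped inverse min(1/permtot, 100); a four-state
crossbridge cycle (N, P, pre- and post-rotation strongly bound states)
with mean-distortion ODEs; single-overlap filament geometry; and a force
balance that evolves sarcomere length SL through
dSL/dt = (Integral_Force + (SL₀ − SL)·viscosity)/mass. Coupling is
one-way: mechanics consumes Ca_i(t) of the final beat only (linearly
interpolated onto its own grid), with no feedback of force or length onto
the EP model, and V(t) is not used by the mechanical equations.

Three points deserve explicit documentation because the printed
formulations are not self-consistent as stated:

- **Regulatory rate constants.** The N→P and P→N base rates are 500 s⁻¹
  and 50 s⁻¹ respectively. The opposite assignment makes the permissive
  state unreachable (P/(N+P) ≤ 1/11 at saturating Ca) and contradicts the
  optimal-condition limit k_n−pT ≫ k_p−nT that defines the force
  normalization.
- **Force-integral sign.** The integral driving dSL/dt accumulates
  −(F_active + F_passive − F_preload) − F_afterload: developed tension
  acts in the shortening direction. With the opposite sign the cell would
  lengthen when it contracts.
- **Distortion normalization.** The mean-distortion ODEs are normalized by
  the constant optimal-condition duty fractions (the same constants that
  normalize active force), not by strain-modified duty fractions — the
  latter couple back into the strain exponentials and self-amplify.

### Contraction mode and the 20 kPa weight

By default the cell contracts against a constant 20 kPa afterload
("weight") with a rigid stop at SL₀: shortening begins only once developed
tension exceeds the weight, which is what makes long EMDs possible at all —
weakly activated cases spend tens of milliseconds climbing to 20 kPa
before the length moves. A series-elastic mode
(F_afterload = KSE·(SL − SL₀)) is available behind the
`contraction_mode` config flag.

Numerics: the (SL, Integral_Force) pair with the printed mass
(5·10⁻⁵ norm·ms²/μm) is a stiff oscillator at √(KSE/mass) ≈ 141 rad/ms
(and in the weighted mode, a near-rigid constraint). That pair is advanced
by backward Euler with the slowly varying force terms frozen over the
step — unconditionally stable, damping only sub-millisecond ringing the
twitch dynamics cannot express — while every other mechanical state uses
explicit Euler at 0.001 ms. Step-halving changes peak tension by < 0.1 %.

### Tension scale

The model's normalized force needs one scale to become kPa; nothing in the
sweep's relative structure depends on it, but the 20 kPa contraction
criterion does. The default is T_max = 250 kPa per unit normalized
force, chosen so the normal cell's
isometric-phase peak tension is ~58 kPa at BCL 600 ms and ~23 kPa at
BCL 1000 ms — inside the experimentally reported range for human
ventricular muscle at body temperature, and above the 20 kPa weight at
both rates, as the normal case must be (it visibly contracts at both
pacing rates). Temperature is 37 °C by default; all transition-rate
temperature factors Q^((TmpC−37)/10) are then exactly 1.

## Biomarkers

Per (case, BCL): AP onset = first V crossing of −40 mV; APD90 = time from
the maximum-upstroke instant to 90 % repolarization of the amplitude
measured from the pre-stimulus resting potential (beat length if the beat
never repolarizes, flagged); max Ca_i = beat maximum; rest Ca_i = final
sample; Ca_i duration = width of the interval above
peak − 0.9·(peak − rest); Ca_i slope = mean upstroke gradient
0.9·(peak − rest)/(time-to-peak − 10 %-rise time), one isolated function
so the convention can be swapped; contraction onset = first crossing of
99 % normalized length, valid only when tension reaches 20 kPa;
EMD = contraction onset − AP onset. All crossings are linearly
interpolated on the 1 ms output grid; missing values are NaN sentinels,
never 0.

The Ca_i-slope convention is the one genuinely ambiguous definition in
the protocol; the mean-upstroke-gradient reading is implemented and
isolated in `cai_attributes`.

## Population sweep and dimensional stacking

The population scales each of the 10 channels to 25/50/75/100 %:
4^10 = 1,048,576 cases, each at both BCLs. Cases are indexed by a
mixed-radix bijection over the canonical channel ordering (Na, CaL, to,
Kr, Ks, K1, pK, pCa, bNa, bCa); sub-sweeps fix unswept channels at 100 %.
Execution is embarrassingly parallel in principle and resumable in
practice (checkpoint CSV, restart skips completed keys, any order yields
the identical sorted table).

Stacking nests five channels per axis (outermost = most significant
digit), making every pixel of a 1024×1024 map one case. The axis order is
chosen by minimizing the roughness cost: the sum of |Δ| over all
axis-aligned neighbor pairs, each pair once, no wrap-around at borders,
and pairs involving a missing-value sentinel contributing 0 (a fixed-
penalty alternative is available). Swapping the axes leaves the cost
invariant, which halves the layout space to 10!/2 classes. Exhaustive
enumeration is provably global and allowed up to a configurable class cap
(default 10,080, i.e. ≤ 8 channels); beyond it a seeded pairwise-swap hill
climb with restarts is used, which recovers the exhaustive optimum on
every ≤ 4-channel surrogate problem tested across 20 seeds. Cost ties
break to the lexicographically smallest (x_order, y_order).

## Surrogate fixtures

`surrogate_fixtures` is a first-class analytic generator that emits
biomarker records with the population's qualitative structure (APD up
with CaL and down with Ks/Kr/K1 plus a CaL×Ks interaction; max Ca_i
shaped by CaL/Ks/bCa/Kr; EMD maximal at intermediate CaL;
no-contraction at the lowest CaL level when bCa is low; optional seeded
Gaussian noise, default off). Its tables are schema-identical to real
sweep output, so all sweep/stacking machinery is testable in milliseconds.
Its effect magnitudes span realistic dynamic ranges (APD to ~580 ms, EMD
to ~83 ms, max Ca_i to ~3 μM) but are synthetic fixtures, not model
claims. What surrogate-based tests show is that the *machinery* (indexing,
tables, maps, optimization) is correct — they say nothing about the ODE
models, which carry their own oracle-based tests.

## Problem sizes used in the shipped analyses

The full 2 × 4^10 experiment and the 10!/2-layout search at 1024² are
cluster-scale and are not rerun here. The shipped acceptance analysis
uses: the normal case at both BCLs (peak-Ca targets); a 256-case
CaL×Ks×Kr×K1 factorial at both BCLs for the APD90 ceiling; and a 64-case
CaL×bCa×Kr factorial with full mechanics at both BCLs for the EMD
ceiling. The APD ceiling is quoted over both pacing rates because the
long-APD corner is restitution-compressed at BCL 600 ms (≈ 503 ms there
vs ≈ 550 ms at BCL 1000 ms in the 4-channel sweep).

## Known limitations

- Single cell only: no tissue coupling, no mechanical-loading component
  of EMD, no restitution-curve or drug-block analyses.
- The transmural cell type, stimulus shape, solver, temperature and
  tension scale of the original population are unspecified upstream;
  the defaults above are this package's documented choices, and the
  printed per-case biomarker values can shift by a few percent under
  other defensible choices.
- With the printed cooperativity constants (perm50 = 0.5, n_perm = 15)
  the force–Ca relation has a sharp activation cliff near ~0.8 μM peak
  Ca_i; cases whose transients peak well below it (e.g. max Ca_i
  ≈ 0.1–0.5 μM) develop normalized tension of 10⁻⁴ and below and cannot
  cross any physiological tension threshold. Such low-Ca configurations
  are non-contracting here, and the population EMD ceiling (~74 ms in
  the shipped scaled-down sweep) sits somewhat below the reported 83 ms;
  the mechanism — marginally supra-threshold cases lifting the 20 kPa
  weight tens of milliseconds after depolarization — is reproduced.
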
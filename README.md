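# cardioemd

Single-cell cardiac electromechanics for conductance-population studies:
which ion-channel conductances, when reduced, prolong the
**electromechanical delay (EMD)** — the time between a ventricular
myocyte's electrical firing and the onset of its mechanical shortening?
Prolonged EMD underlies dyssynchronous heart failure, and channel
remodeling or block changes each conductance independently, so the
question is inherently a population one.

The package is for computational cardiac electrophysiologists and
systems-biology modelers. It implements:

- the **ten Tusscher–Panfilov human ventricular ionic model** with a
  reduced Markov ryanodine receptor (R̄ = R + O,
  O = k₁Ca_SS²R̄/(k₃ + k₁Ca_SS²), I_rel = V_rel·O·(Ca_SR − Ca_SS)),
  three-compartment Ca²⁺ dynamics, and per-channel maximum-conductance
  scaling over the ten sarcolemmal currents
  (I_Na, I_CaL, I_to, I_Kr, I_Ks, I_K1, I_pK, I_pCa, I_bNa, I_bCa);
- a **Rice-type myofilament model** (troponin binding, cooperative N↔P
  regulatory switching with Hill coefficient n_perm = 15, a four-state
  crossbridge cycle with mean-distortion dynamics, and sarcomere-length
  evolution against a 20 kPa afterload), driven one-way by the EP model's
  Ca_i(t);
- **biomarkers**: APD90, max/rest Ca_i, Ca-transient duration and slope,
  AP onset (V ≥ −40 mV), contraction onset (normalized length ≤ 0.99 with
  tension ≥ 20 kPa), and EMD = contraction onset − AP onset;
- a resumable **4-level × 10-channel factorial sweep**
  (4¹⁰ = 1,048,576 cases at two pacing rates, 600 and 1000 ms), and
- **dimensional stacking**: bijective nesting of five channels per map
  axis with an axis-order optimization that minimizes the summed absolute
  neighbor difference, so the most influential channels surface on the
  outermost axis positions.

See `docs/methods.md` for the model equations, parameter choices and
numerical scheme.

## Worked example

Run the normal cell (every conductance at 100 %) at BCL 600 ms:

```bash
cardioemd case --bcl 600
```

```
case_id: 1048575
bcl_ms: 600.0
apd90_ms: 296.1503294203715
max_cai_mM: 0.0012456386241167308
rest_cai_mM: 0.00012584483314197203
cai_dur_ms: 346.4887517535392
cai_slope_mM_per_ms: 4.677032565464022e-05
emd_ms: 33.26904434189186
contracted: True
diverged: False
```

Reading: after 50 pre-paced beats the final action potential lasts
296 ms (APD90); the Ca transient peaks at 1.246 μM and returns to a
0.126 μM diastolic level; developed tension exceeds the 20 kPa weight and
the cell shortens past 99 % of its resting length 33.3 ms after the
membrane potential crossed −40 mV — that 33.3 ms is the normal-case EMD.

A scaled-down sweep and its optimized stacking map:

```bash
cardioemd sweep --channels CaL,Ks,Kr,K1 --bcl 600 --no-mechanics --out apd.csv
cardioemd stack --results apd.csv --bcl 600 --biomarker apd90_ms \
    --mode exhaustive --out apd_map.png --grid apd_map.tsv
```

The map places CaL on an outermost axis: raising CaL conductance and
lowering Ks/Kr/K1 lengthens APD, the same repolarization-reserve pattern
the population analysis quantifies. The surrogate generator
(`cardioemd surrogate`) emits schema-identical tables without ODE cost
for exercising the sweep/stacking machinery.

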
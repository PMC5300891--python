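# Methods

## The reaction network

The model describes a bivalent protein (the ZBP1/IMP1 KH3-KH4 di-domain)
binding a bipartite RNA (the β-actin Zipcode) through six species — free
RNA R, free protein P, two open 1:1 complexes C3/C4 (one domain engaged),
the closed (RNA-looped) 1:1 complex CC, and a 2:1 protein:RNA complex D —
connected by mass-action kinetics:

- R + P ⇌ C3 (kon3/koff3) and R + P ⇌ C4 (kon4/koff4);
- ring closure C3 ⇌ CC (kC4/koff4) and C4 ⇌ CC (kC3/koff3): the
  still-free domain of a singly-bound protein captures its site on the
  *same* RNA, a first-order step whose rate subsumes the conformational
  search of the looping RNA;
- 2:1 formation C3 + P ⇌ D (kon4/koff4) and C4 + P ⇌ D (kon3/koff3):
  each protein in D engages exactly one site, so single-domain constants
  apply.

Assumptions: well-mixed dilute solution; no 1:2 complex (one protein
bridging two RNAs — irrelevant at sub-nanomolar RNA against micromolar
single-site Kds); closure rates independent of spacer length (a fixed RNA
is modelled); and the engaged-domain off-rates are the same in every
context (open complex, closed complex, 2:1 complex).

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| kon3 | KH3 association | 3.0e4 | M⁻¹s⁻¹ |
| koff3 | KH3 release | 0.046 | s⁻¹ |
| kon4 | KH4 association | 1.4e5 | M⁻¹s⁻¹ |
| koff4 | KH4 release | 0.13 | s⁻¹ |
| kC3 | closure, KH3 second | 2 | s⁻¹ |
| kC4 | closure, KH4 second | 9.333 | s⁻¹ |
| P_tot | total protein | 0.2e-6 | M |
| R_tot | total RNA | 0.4e-9 | M |

The kon/koff values are the BLI-measured single-domain constants at 25 °C;
the concentrations are cell-like estimates (fibroblast ZBP1 0.05–0.5 µM;
~500 β-actin mRNAs per neuron → sub-nanomolar). The closing rates come
from `derive_closing_rates`: with the closed complex dominating the bound
population, the overall dissociation constant satisfies
Kd_overall ≈ Kd3·koff4/kC4 ≈ Kd4·koff3/kC3, inverting to
kC3 = Kd4·koff3/Kd_overall and kC4 = Kd3·koff4/Kd_overall. With the
measured Kd_overall = 20 nM these give 2.14 and 9.97 s⁻¹; the shipped
default rounds kC3 to 2 and sets kC4 = 2·kon4/kon3 = 9.333 so the
thermodynamic cycle stays consistent to 4e-5 (the
`cycle_consistency_ratio`, (kon3·kC4)/(kon4·kC3), must equal 1 for a true
equilibrium; `derive_closing_rates` output satisfies this exactly).

All internal units are SI (molar, seconds); configuration files may tag
values with nM/µM-style units, converted on load.

## Numerical choices

**Integration.** Classical fixed-step RK4 (`dt = 0.01 s` by default). The
fastest default process is ~9.5 s⁻¹, so dt·λ_max ≈ 0.1, far inside the
stability interval; the integrator refuses any step with dt·λ_max ≥ 2.5,
estimating λ_max as the largest per-species loss rate at the initial
state. Halving dt changes final concentrations by < 1e-6 relative (tested).
The inner loop is numba-compiled, with a pure-Python fallback. The rate
law is written with symmetric pairwise grouping so that exchanging the
KH3/KH4 labels permutes trajectories bitwise-exactly.

**Equilibrium detection.** Equilibrium is declared when
|dC/dt|·(1 s)/max(C, 1e-15 M) < 1e-9 for every species. This is a strict
criterion: at base conditions the concentrations are visually settled by
~150 s, but the residual drift only decays below 1e-9 around 700 s, so
`run_to_equilibrium` defaults to a 2000 s horizon while plain `integrate`
keeps a 500 s one (the interesting dynamics are over well before).
`time_to_equilibrium` is reported as the earliest time the closed complex
is within 1% of its final value (~130 s at base conditions).

**Steady-state solvers.** Two independent algebraic routes cross-check
the integrator: (i) a 5×5 linear solve of the complex stationarity
conditions plus RNA conservation at fixed free protein, iterated with the
protein-conservation update to a 1e-12 fixed point (valid for any rates,
including detailed-balance-violating sets whose steady state carries a
circulating flux); (ii) a closed form built purely from equilibrium
constants, valid only for cycle-consistent parameters. Protein depletion
by the RNA is handled exactly, though it is ~0.2% at base conditions.

**Dissociation protocol.** Free protein is clamped to zero at every RK4
stage (wash conditions — released protein cannot rebind), leaving closure
and all unimolecular dissociations active; protein mass is deliberately
not conserved there. The decay of total bound RNA is fitted with
A·e^(−kt)+c. The analytic companion, the escape-probability rate
k_eff = koff4·koff3/(koff3+kC4) + koff3·koff4/(koff4+kC3), carries an
O(koff/kC) error: the fitted decay equals the exact slow eigenvalue of
the clamped network, and the two agree to ~3% at the default parameters
(closure ~15× faster than release) and to better than 5% once closure is
≳40× faster; at a 20× ratio the deviation can still reach ~6%.

**Sweeps.** The closing-rate sweep co-scales kC4 with kC3 by default so
the cycle stays consistent; this reproduces the reduced-closing reference
results (57% bound, apparent Kd ≈ 153 nM at kC3 = 0.2 s⁻¹). The variant
holding kC4 fixed (60% / 131 nM) sits behind `preserve_ratio=False`.
Apparent Kd is defined as P_free·R_free over all protein-bound RNA; among
candidate definitions this is the one that reduces to koff/kon for a
single 1:1 reaction and reproduces the 20.5 nM base-case value.

## BLI analysis and the synthetic generator

The fitting pipeline is the classical 1:1-Langmuir workflow: per-trace
mono-exponential association fits give kobs; kon is the slope of kobs vs
analyte concentration (intercept estimates koff); Kd comes from the
equilibrium-response hyperbola Req = Rmax·P/(P+Kd); koff = Kd·kon is
cross-checked against direct dissociation fits (flagged consistent within
25%). The 1:1 model is applied to the bivalent analyte deliberately: fast
closure makes the association phase effectively single-exponential and
the closure-limited off-rate dominates dissociation. The equilibrium
response per trace is the *fitted asymptote* (A + c) of the association
fit rather than a raw tail average: the slowest trace in a titration
typically stops a few percent short of its plateau, and a tail average
would propagate that bias straight into the Kd. Fits are unweighted least
squares (no error model is assumed).

The generator fabricates sensorgrams from the same closed forms
(association Req·(1−e^(−kobs·t)), exponential dissociation) with i.i.d.
additive Gaussian noise, under three presets: the di-domain construct
(apparent kon 1.6e5 M⁻¹s⁻¹, koff 0.0033 s⁻¹, 5–160 nM two-fold series,
900 s/900 s phases) and the two single-functional-domain constructs
(125–8000 nM, shorter phases matched to their faster kinetics). Durations
are chosen so every trace reaches ≥ 95% of its plateau. Datasets are
byte-reproducible from (preset, noise_sd, seed).

Because generator and fitter share the 1:1 functional form, passing
recovery tests demonstrates the correctness of the fitting machinery and
its noise robustness — not that real multi-phase, drifting,
transport-limited sensorgrams would be fit without bias. Real-data
effects deliberately not emulated: sensor loading variability, baseline
drift, reference-channel subtraction, mass-transport limitation.

## Test problem sizes

The randomized cross-route grid uses 10–20 parameter draws within 10× of
the reference rates (cycle-consistent by construction, plus one
inconsistent set checked against the linear solver only); noisy-recovery
statistics use 50 seeded datasets at 2% noise; dissociation-regime checks
use 6 draws. The whole suite runs in a few seconds on one CPU.

## Known limitations

- Closure rates are effective first-order constants; no spacer-length or
  RNA-structure dependence is modelled.
- The 2:1 complex assumes independent, context-free single-domain
  binding; negative/positive cooperativity between the two proteins is
  not representable.
- The escape-rate formula degrades near the weak-avidity boundary (see
  above); use the simulated dissociation fit there.
- The BLI model is strictly 1:1; it reports *apparent* constants for the
  bivalent analyte, matching the standard instrument-software analysis.
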
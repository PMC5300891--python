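# loopbind

Kinetic modelling of bivalent protein–RNA recognition with RNA looping,
built around the interaction of the ZBP1/IMP1 KH3-KH4 di-domain with the
28-nt β-actin Zipcode element, plus the biolayer-interferometry (BLI)
analysis that supplies the model's rate constants.

## Who this is for

Biophysicists and RNA biologists who want to ask quantitative questions
about multivalent RNA-binding proteins: how much avidity does a second
domain buy, how fast does the complex really fall apart, and whether the
bound fraction in a cell is controlled by protein or by RNA concentration.

## The model

A di-domain protein P binds a bipartite RNA R carrying one cognate site
per domain. Six species and six rate constants:

```
R + P  ⇌  C3      kon3 / koff3      KH3 engaged (open 1:1)
R + P  ⇌  C4      kon4 / koff4      KH4 engaged (open 1:1)
C3     ⇌  CC      kC4  / koff4      KH4 closes the ring (looped 1:1)
C4     ⇌  CC      kC3  / koff3      KH3 closes the ring
C3 + P ⇌  D       kon4 / koff4      second protein binds → 2:1 complex
C4 + P ⇌  D       kon3 / koff3
```

The ring-closure rates kC3/kC4 are intramolecular and not directly
measurable; they are reconstructed from the overall di-domain dissociation
constant and the single-domain kinetics,

```
kC3 = Kd4·koff3 / Kd_overall        kC4 = Kd3·koff4 / Kd_overall
```

with Kd_i = koff_i/kon_i, which automatically closes the thermodynamic
cycle (detailed balance: kC4/kC3 = kon4/kon3). When free protein is washed
away, the closed complex escapes at approximately

```
k_eff = koff4·koff3/(koff3 + kC4) + koff3·koff4/(koff4 + kC3)
```

— two orders of magnitude slower than either single domain releases,
which is the avidity effect in kinetic form.

The package provides mass-action RK4 time courses, direct steady-state and
detailed-balance solvers (three independent routes that are cross-checked
against each other), apparent-Kd and fraction-bound summaries,
concentration and closing-rate sweeps, a 1:1-Langmuir BLI fitting pipeline
(kobs slope → kon; response titration → Kd; koff = Kd·kon with a direct
dissociation cross-check), and a synthetic sensorgram generator with known
ground truth.

## Worked example

```python
import loopbind as lb

params, conditions = lb.zipcode_defaults()   # 0.2 uM protein, 0.4 nM RNA
summary = lb.run_to_equilibrium(params, conditions)
print(f"fraction bound   : {summary.fraction_bound:.3f}")
print(f"apparent Kd      : {summary.Kd_app * 1e9:.1f} nM")
print(f"time to plateau  : {summary.time_to_equilibrium:.0f} s")

decay = lb.dissociation_timecourse(params, summary.state,
                                   lb.IntegratorSettings(dt=0.01, t_end=1500))
fit = lb.exponential_fit(decay.times, decay.bound_rna, "decay")
print(f"wash-out off-rate: {fit.rate:.4f} /s")

traces, truth = lb.generate_bli_dataset("didomain", noise_sd=0.02, seed=7)
result = lb.analyze_bli_dataset(traces)
print(f"BLI fit          : kon = {result.kon:.3g} /M/s, "
      f"Kd = {result.Kd * 1e9:.1f} nM, koff = {result.koff_from_kd_kon:.2e} /s")
```

prints

```
fraction bound   : 0.907
apparent Kd      : 20.5 nM
time to plateau  : 130 s
wash-out off-rate: 0.0033 /s
BLI fit          : kon = 1.59e+05 /M/s, Kd = 20.6 nM, koff = 3.28e-03 /s
```

At cell-like concentrations ~91% of the RNA is bound, almost entirely as
the looped closed complex; the apparent Kd (20.5 nM) matches the measured
di-domain affinity even though each single domain binds only with
micromolar affinity; and a noisy synthetic BLI titration round-trips to
its ground-truth constants.

A CLI mirrors the library (`loopbind simulate | equilibrium | sweep |
derive-kc | bli-fit | synth | scenario`); try
`loopbind scenario --name no_closing --out out/`.

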
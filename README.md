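# emulrelax

Low-field NMR relaxometry analysis of oil-in-water emulsions: from
inversion-recovery and CPMG signal traces to per-phase activation
energies of molecular rotation.

## The problem

Time-domain NMR at low field (here 15 MHz proton frequency) measures
relaxation time constants rather than spectra. In a two-phase
oil-in-water emulsion — e.g. animal fat dispersed in a starch paste —
both the spin-lattice (T1) and spin-spin (T2) relaxation curves are
biexponential: the short components (T11, T21) belong to the oil
protons and the long components (T12, T22) to the water phase. Tracking
these components while cooling the sample from 90 °C to 0 °C reveals
the molecular dynamics of each phase separately, and in particular the
energy barrier ΔEa that hinders molecular rotation — a quantity that
food scientists use to compare how different stabilizers (modified
starches, emulsifiers) structure the water and oil phases.

## The model

Three standard relations connect the measurements to ΔEa:

1. **Dipolar relaxation (BPP)** — for isotropic rotation with a single
   mean correlation time τc at angular frequency ω = 2πf:

       R1 = 1/T1 = (6/20) K [ τc/(1+(ωτc)²) + 4τc/(1+(2ωτc)²) ]
       R2 = 1/T2 = (3/20) K [ 3τc + 5τc/(1+(ωτc)²) + 2τc/(1+(2ωτc)²) ]

   with K = (μ0/4π)² γ⁴ ħ²/r0⁶ the dipolar prefactor. The ratio
   R2/R1 = T1/T2 is independent of K, ≥ 1, and strictly increasing in
   τc, so each temperature's (T1, T2) pair for a phase inverts uniquely
   to a correlation time without knowing r0.

2. **Fast-exchange averaging** — when proton pools within a phase
   exchange quickly, the observed rate is the fraction-weighted mean
   1/T = Σ pᵢ/Tᵢ (`observed_rate`).

3. **Arrhenius law** — thermally activated rotation obeys
   τc = τ0 exp(ΔEa/RT), so an OLS regression of ln τc on 1/T yields
   ΔEa (kJ/mol) from the slope.

The pipeline composes them: two-component fits of each IR and CPMG
trace → short/long components assigned to oil/water → per-phase τc from
the T1/T2 ratio → per-phase Arrhenius fit → an activation-energy table.
Because no public raw emulsion traces exist, the package includes a
seeded simulator (`emulrelax.simulate`) that generates temperature
series with known ground truth, and ships the measured fatty-acid
profiles of beef and pork fat plus published per-phase activation
energies as reference fixtures.

## Worked example

```python
from emulrelax import run_pipeline

result = run_pipeline({"simulate": {"seed": 1, "snr": 100.0}})
print(result.summary())
```

```
Activation energies of rotational motion (kJ/mol):
  synthetic 0.17 synthetic   oil: 24.5 ± 0.3
  synthetic 0.17 synthetic water: 15.1 ± 0.2
```

The simulated emulsion has true ΔEa = 25 kJ/mol (oil) and 15 kJ/mol
(water); at a signal-to-noise ratio of 100 with 5 accumulations the
pipeline recovers both within a few percent, and the ± values are the
OLS slope standard errors. Individual stages are inspectable:

```python
print(result.fits[(("synthetic", 0.17, "synthetic"), "water")].summary())
```

```
Arrhenius fit (water), n = 10
  dEa   = 15.08 +/- 0.19 kJ/mol
  tau_0 = 1.933e-11 +/- 1.4e-12 s
  R^2   = 0.998764
```

The same flow is available from the shell:

```sh
emulrelax simulate --seed 1 -o ds/        # traces + ground-truth sidecar
emulrelax fit -d ds/ -o components.csv    # biexponential fits per temperature
emulrelax analyze -c pipeline.yaml -o ea.csv
emulrelax fattyacids --fat beef           # packaged profile group sums
```

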
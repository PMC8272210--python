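# Methods

## Model and assumptions

The package treats an oil-in-water emulsion as two **non-exchanging
proton pools** (oil, water). Each pool relaxes independently with its
own T1 and T2, so an inversion-recovery curve is

    M(τ) = M0 [1 − 2α Σᵢ pᵢ exp(−τ/T1ᵢ)],   Σ pᵢ = 1,

and a CPMG echo train is A(t) = A0 Σᵢ pᵢ exp(−t/T2ᵢ). The inversion
efficiency α is fixed at 1 (ideal 180° pulse) by default; an opt-in fit
constrains α ∈ [0.8, 1]. Cross-relaxation and chemical exchange between
oil and water protons are out of scope: the phases are spatially
separated and their relaxation behaviour is treated as independent.

Within a pool, relaxation is governed by intramolecular dipolar
coupling modulated by isotropic rotational diffusion with a **single
mean correlation time** τc (the classic dipolar spectral-density
model). No distribution of correlation times (Cole–Cole), internal
motion (Lipari–Szabo) or inverse-Laplace T2 spectrum is modelled —
discrete exponential components only. τc follows the Arrhenius law
τc = τ0 exp(ΔEa/RT); curvature diagnostics beyond R² (VFT/WLF
behaviour) are not attempted.

## Correlation-time extraction

Two routes invert the dipolar model, selected by the pipeline `mode`:

- **`ratio` (default)**: τc from R2/R1 = T1/T2. The dipolar prefactor K
  cancels, so no internuclear distance r0 is required — important
  because r0 is not measurable in these systems. The ratio is strictly
  increasing in τc; the root is found by bisection on ln τc (tolerance
  1e−12, i.e. relative ~1e−12 on τc).
- **`r1`**: τc from R1 alone. Requires K (supplied via r0, default
  1.8 × 10⁻¹⁰ m, a typical intramolecular proton-pair distance) and an
  explicit `branch` because R1 is double-valued around its maximum at
  ωτc ≈ 0.616. There is no default branch: emulsion phases can cross
  the maximum within 0–90 °C, which is precisely why `ratio` is the
  headline route.

**Sub-unity ratios.** Noise at high temperature can push an observed
T1/T2 marginally below 1 (physically impossible). Ratios in [0.9, 1)
are clamped to 1 + 1e−9, flagged in the pipeline diagnostics
(`ratio_clamped`) and reported as upper-limit correlation times; ratios
below 0.9 abort with an error, since that signals a data problem rather
than noise.

## Curve fitting

Multiexponential least squares is notoriously ill-conditioned, so the
fits are initialised deterministically (reproducibility over cleverness):

1. a log-spaced grid of candidate time constants over
   [times[1]/10, 10·times[−1]] (25 points for ≤ 2 components, 14 for 3);
2. for every candidate combination, non-negative linear least squares
   (NNLS) for the amplitudes — a variable-projection step;
3. full nonlinear refinement with `scipy.optimize.least_squares` (TRF,
   tolerances 1e−14) on (ln Tᵢ, aᵢ), bounds as above, amplitudes ≥ 0.

Fractions are amplitude shares, renormalised to sum to 1 exactly.
Weighting is unit by default and inverse-variance when the trace
carries a known noise σ. Standard errors come from the Jacobian at the
optimum (delta method for ln T → T). Non-convergence is reported via
`converged=False`, never silently replaced. Components closer than a
factor 1.2 in time constant trigger a collapse warning.

**Model-order selection** (`select_n_components`, opt-in) compares
small-sample AICc across 1..max components with the RSS floored at the
machine-precision scale of the signal, so exact nested fits tie and the
tie breaks toward fewer components. A larger model is accepted only if
it improves AICc *and* its components are genuinely resolved (adjacent
ratio ≥ 1.2, no vanishing fraction); this is what makes a T-ratio-1.05
biexponential correctly collapse to one component. The pipeline default
is two components throughout, matching the two-phase physics of an
emulsion; automatic selection is for exploratory use.

## Arrhenius regression

OLS of ln τc on 1/T (statsmodels), slope × R = ΔEa in J/mol, reported
in kJ/mol. The quoted uncertainty is the **OLS slope standard error** —
published tables in this field rarely state whether ± means SE, SD or
replicate spread, so the choice is made explicit here. Optional
inverse-variance weighting on ln τc (delta method from upstream τc
uncertainties) is available but off by default. Display rounding is
half-up to one decimal; CSV output keeps full precision.

## The simulator

`emulrelax.simulate` emulates the measurement protocol the analysis
expects: a 15 MHz spectrometer, temperatures within 0–90 °C,
inversion-recovery and CPMG sequences, five-fold accumulation
averaging, additive i.i.d. Gaussian amplitude noise with s.d.
M0/(SNR·√n_accumulations). Delay/echo grids are log-spaced, 32 points
(IR) and 48 points (CPMG), spanning [0.1·min T, 4·max T] of the true
time constants at each temperature — mirroring how an operator retunes
sequence parameters per sample and temperature. An opt-in uniform
temperature jitter (±0.5 °C scale) models thermostat error; it is off
by default.

The **default preset** (`paper_like_spec`): oil ΔEa = 25 kJ/mol,
τ0 = 10⁻¹² s, K = 4.2 × 10⁹ s⁻², p = 0.2; water ΔEa = 15 kJ/mol,
τ0 = 2 × 10⁻¹¹ s, K = 4.7 × 10⁸ s⁻², p = 0.8; ten temperatures evenly
spaced over 0–90 °C. These values were chosen once so that (a) the
simulated components land in the regimes published for
starch-stabilised emulsions — oil T2 of ~8–46 ms, water T2 of
~190–540 ms, water T1 ≈ 0.6 s, short-oil/long-water ordering at every
temperature; (b) ωτc is of order 0.3–6 across the range, so the T1/T2
ratio carries usable τc information (in true extreme narrowing the
ratio route is ill-conditioned by construction); and (c) the proton
split reflects a 1/4 oil:water mass ratio. The preset is labelled
approximate: it is *not* ground truth for any real sample.

**What the simulator does not emulate** — and hence what passing tests
do not demonstrate about real data: pulse miscalibration and B1
inhomogeneity, baseline drift, diffusion in field gradients, fat
crystallisation and polymorphic transitions on cooling, exchange
between pools, and non-single-τc spectral densities. Recovery of the
preset's ΔEa shows the estimator chain is correct and stable under
Gaussian noise, not that real emulsions obey the model.

## Numerical choices

- Bisection/Brent root-finding always operates on ln τc so tolerances
  are relative across 14 decades.
- All temperatures are kelvin internally; Celsius only at I/O
  boundaries (T(K) = T(°C) + 273.15).
- Physical constants are CODATA 2018 values in `emulrelax.constants`;
  gas constant R = 8.314462618 J mol⁻¹ K⁻¹.
- Trace RNG streams are keyed by (seed, temperature in mK, sequence
  kind), so datasets are bit-reproducible and independent of generation
  order.
- Phase assignment is by ordering (short = oil, long = water) and
  refuses ties and non-two-component fits rather than guessing.

## Fixtures

- `data/fatty_acid_profiles.csv`: gas-chromatography fatty-acid
  profiles (percent) of the beef and pork fats; beef totals ≈ 99.99 %,
  pork ≈ 97.08 % (minor acids below detection are omitted by the
  assay, hence totals are validated against a wide [95, 101] band with
  a warning only). One documented inconsistency: prose summaries of
  pork oleic+linoleic state 49.0 % while the profile sums to 48.947 %
  (→ 48.9); the fixture keeps the profile values.
- `data/activation_energy_reference.csv`: published per-phase
  activation energies for emulsions stabilised with two modified
  starches at three concentrations and two fats (24 entries). They
  derive from undeposited spectrometer data and are **not recomputable
  by this package**; they serve schema and round-trip tests only.

## Problem sizes

Default analyses use 10 temperatures × (32 IR + 48 CPMG) points;
noise-consistency checks use 100 seeded replicates of a 200-echo train
at SNR 200. These sizes put every estimator comfortably in its
asymptotic regime while keeping a full pipeline run under a second.

## Known limitations

- The two-component default hard-wires the two-phase interpretation;
  systems with a third pool (e.g. bound-water fractions resolved at
  higher field) need `n_components=3` and explicit phase mapping.
- SE of ΔEa ignores the uncertainty correlation induced by fitting T1
  and T2 from the same trace pair.
- The `r1` mode inverts only R1 and assumes the chosen branch holds at
  every temperature of a series.
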
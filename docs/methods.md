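# Methods

This note documents the models implemented in `teatk`, the defaults and
the numerical choices, in enough detail to judge what the tests do and
do not demonstrate.

## Kinetic model

State variables (amounts in ng per kg body weight, time in hours):
gut depot `a_gut`, central free TeA `a_central`, phase-II metabolites
`a_met`, and cumulative urinary amounts `q_u` (free) and `q_umet`
(metabolites).  The ODEs are the linear cascade

```
a_gut'     = -k_gutabs a_gut
a_central' =  k_gutabs a_gut - k_el a_central
a_met'     =  k_met a_central - k_umet a_met
q_u'       =  k_u a_central
q_umet'    =  k_umet a_met
```

with `k_el = Cl_tot/Vd`, `k_u = k_ufrac k_el`, `k_met = (1-k_ufrac)
k_el`, `k_umet = Cl_met/Vd_met`.  Absorption is complete and there is
no fecal route, so mass balance `a_gut + a_central + a_met + q_u +
q_umet = dose` holds identically; the closed form maintains it to
<1e-9 of the dose and agrees with an LSODA integration (rtol 1e-10)
to a mixed tolerance of 1e-6.

Observables: blood concentrations `c_free = a_central/Vd` and
`c_total = c_free + F_gluc a_met/Vd_met` (ng/mL; hydrolysis was
applied to both matrices, so "total" includes the glucuronides in
blood as in urine); urinary void masses are interval differences of
`q_u` and `q_u + F_gluc q_umet`, scaled by body weight.

Numerical choices:

* Coincident rate constants (removable singularities of the
  exponential superposition) are separated by a relative nudge of
  1e-7 when closer than 1e-9 — far below the verification tolerance.
* Void masses difference the exponential terms directly rather than
  the cumulative amounts, which would cancel catastrophically for
  late voids at the cumulative asymptote.
* `t_max` uses the two-exponential peak formula with the limit
  `1/k_el` at `k_gutabs = k_el`.

`F_met` is reported as the derived quantity `(1-k_ufrac) F_gluc` — the
fraction of the dose recovered in urine as measurable conjugates.
This derivation is a package choice; other conventions exist.

## Identifiability: the flip-flop constraint

The observable set is **exactly invariant** under exchanging the
absorption and elimination rates with a compensating volume,
`(k_gutabs, k_el, Vd) -> (k_el, k_gutabs, Cl_tot/k_gutabs)`: blood
concentrations, urinary masses, and all metabolite observables are
unchanged.  The posterior of the unconstrained model is therefore
bimodal with likelihood-equal modes, separated only by the priors.
The model restricts individual parameters to the absorption-dominant
branch `k_gutabs > k_el`, which is the physiologically standard
resolution and is consistent with the early (~0.2 h) observed blood
peak.  The hierarchical density carries the corresponding probit
normalization in the population-mean and SD conditionals.

## Population model and priors

Individual log parameters are normal around a population mean,
independently per parameter (no cross-parameter correlation and no
covariate effects).  Fractions (k_ufrac, F_gluc) are truncated to
(0, 1].  Fitting works on the rate parameterization (k_umet) and
reports Cl_met = k_umet·Vd_met per draw.

Priors (all overridable via `PopulationPrior`):

* Population GMs: very diffuse lognormals — GM₀ 0.37 (Cl_tot),
  0.30 (Vd, Vd_met), 0.5 (k_umet, fractions), 4.9 (k_gutabs), each
  with GSD 9.97; fractions truncated to (0.01, 1].  The GSD value is
  read as a (deliberately uninformative) geometric standard deviation.
* Population variability: half-normal on the log-scale SD with scale
  ln 2.5.
* Error GSDs: log-uniform on [1.01, 3], one per observation class
  (blood-free, blood-total, urine-free, urine-total).

The likelihood is the normal density of the log residuals with
SD = ln(error GSD); the constant data Jacobian of the lognormal is
dropped (it involves no sampled parameter).  Censored observations
contribute `log Φ((ln LOD - ln pred)/σ)`; a prediction that has
decayed to numerical zero is treated as certainly below the LOD, and a
non-positive prediction for an uncensored observation yields a -inf
log likelihood rather than an exception.

## Sampler

Adaptive Metropolis-within-Gibbs:

* individual log parameters, coordinate-wise, vectorized across
  subjects (per-subject likelihoods are independent given the
  hierarchy);
* population means and log-SDs against the hierarchical density with
  explicit truncated-normal normalizations;
* error GSDs against the pooled residuals (cached log predictions);
* a joint translation move (one population mean together with all its
  individual values) for mixing along the hierarchy; and
* (Cl_tot, Vd) pair moves at fixed k_el, per subject and population
  level — either coordinate alone changes the elimination rate and is
  vetoed by well-fit urinary data, so this ridge needs a dedicated
  move.

Step sizes adapt in batches only during burn-in (Robbins–Monro toward
0.44 acceptance); the post-burn-in chain is a fixed-kernel Markov
chain.  Chains start from noncompartmental heuristics (trapezoid AUC
for clearance, terminal slope for k_el, urinary recovery for k_ufrac)
with lognormal jitter for overdispersion; initialization affects
burn-in length only.  Convergence is monitored with the classic
split-chain Gelman–Rubin statistic (threshold 1.2); constant identical
chains give 1.0 and constant different chains give infinity by
construction.

Default production settings are 4 chains × 20,000 iterations with the
first half discarded.  The test suite runs reduced sizes chosen for
R-hat ≲ 1.1 on the default synthetic trial: 4 × 8,000 for the
reference fit and 2 × 5,000 per replicate in the 20-replicate recovery
experiment.  Recovery is assessed as aggregate 90%-interval coverage
across all seven population GMs and replicates (a per-parameter
threshold at 20 replicates would have a large false-failure
probability even for perfectly calibrated intervals).  The absorption
rate is the least recoverable parameter: at the trial dose absorption
is essentially complete before the second blood sample, so its
posterior is bounded below by the data but only weakly above.

## Synthetic trial generator

Emulates a 10-subject single-bolus study at 1500 ng/kg bw over 48 h:
13 blood samples per subject (5 min–48 h, dense within the ~13 h
detectability window) and 11 urine voids, each measured unhydrolyzed
("free") and after hydrolysis ("total").  Generating population values
are the study-like posteriors: GM (GSD) Cl_tot 1.58 (1.60) L/h·kg, Vd
4.35 (1.67) L/kg, Vd_met 7.36 (1.29) L/kg, Cl_met 33.7 (1.16) L/h·kg,
k_gutabs 23.9 (1.14) 1/h, k_ufrac 0.212 (1.49), and F_gluc 0.098
(1.95), back-derived from the conjugate recovery fraction 0.077.
Measurement error is lognormal with GSD 1.25 (blood) and 1.20 (urine)
— the standard population-TK error convention; the study reports no
error model.  LODs are 0.02 ng/mL in blood and 1 ng/mL in urine
(converted per void to mass via the void volume), chosen so the free
blood signal censors at roughly 8–13 h, matching the reported
detectability window.  Body weights are uniform 55–95 kg and void
volumes lognormal around 150 mL (GSD 1.3) — plausible adult values;
the study reports neither.

What the generator does **not** emulate: the trial's actual per-subject
sampling schedule (unpublished), dietary background contamination,
fecal sampling (all below LOD in the study), oxidative/reductive
metabolites, and any non-lognormal error structure.  Passing recovery
tests therefore demonstrate internal consistency of the fit under the
assumed error model, not robustness to real-data misspecification.

## iTTC derivation

All factors are lognormal `UncertainFactor(P50, P95/P50)`:

| Component | P50 | Spread | Source convention |
|---|---|---|---|
| NOEL (blood C_ss) | GM of 22/8.5/8.3 nmol/L = 11.6 | GSD from the population (n-denominator) SD of the logs = 1.57 | the sample-SD alternative is inconsistent with the quoted interval |
| AF_PoD-NOAEL | 0.333 | P95/P50 = 1.567/0.333 | WHO/IPCS chronic continuous endpoint |
| AF_interTD | 1 | GSD 1.95^(1/√2) | TD half of the combined interspecies GSD |
| GSD_intraTD | 10^0.221 | P95/P50 = 2.85 | see below |

The intraspecies TD distribution is implemented as a lognormal on the
GSD itself — median 10^0.221 with the 2.85 spread ratio applied on the
log10 scale.  This is the reading that reproduces the quoted quantiles
of the GSD (0.58/1.66/4.68), of the derived factor (0.28/3.26/36.16),
and of both final iTTC distributions; the alternative reading
(lognormal on log10 GSD) does not.  It admits GSD draws below 1, which
the intraspecies combination handles via the squared-log rule
`exp(sqrt(Σ (ln g)²))`.

The intraspecies factor is `GSD^z` with z = 2.326 (1% incidence; a
random individual draws z ~ N(0,1)).  Urine: NOEL × Cl_tot GM (1.58) ×
k_ufrac GM (0.212) × 24; intraspecies GSD combines 1.60 (Cl_tot), 1.49
(k_ufrac) and the TD draw.  The TK GSDs are fixed at their posterior
medians by default; `derive_ittc_urine(tk_gsd_samples=...)` propagates
posterior draws instead.  Default 1e5 Monte Carlo draws; repeated-seed
medians vary by <3%.

## Risk screening

Reverse dosimetry at steady state: oral dose = plasma concentration ×
1.56 L/h·kg × 24 (plasma path) or urinary excretion / 0.212 (urine
path); urinary concentrations first form a 24-h excretion with the
default volume 1766.53 mL and the cohort body weight.  The dose
back-calculation clearance (1.56) and the posterior-median clearance
(1.58) are intentionally separate constants, as both appear in the
source material.  Whether the 0.73 blood–plasma partition ratio should
enter the plasma dose path is internally inconsistent there; the
default omits it (reproducing the published cohort doses) and
`ScreeningConstants(apply_partition_to_dose=True)` exposes the
alternative.  HQ_iTTC for plasma cohorts divides the plasma molar
concentration by the blood prob-iTTC (0.5 nmol/L default), matching
the published values within rounding.  TeA molar mass: 197.23 g/mol
(C10H15NO3).

The nested iIMOE screen uses n_outer = 2000 uncertainty draws (each
with a with-replacement cohort resample) × n_inner = 5000 individuals
(random z, resampled exposure); the output is the outer-loop
distribution of the population fraction with iIMOE below 1.  With all
spreads collapsed the screen degenerates to a deterministic exceedance
indicator.  Cohorts published only as summary statistics can be
reconstructed by a lognormal fit to the median and quartiles, clipped
to the published range; such cohorts are flagged `reconstructed` and
are synthetic stand-ins adequate for screening magnitudes only.

## Known limitations

* n = 10 subjects bounds what any fit can say about population
  variability; the metabolite parameters (Vd_met, Cl_met) are only
  weakly identified individually (their posteriors are wide, as in the
  study), and the absorption rate is bounded below much more sharply
  than above.
* The error model (lognormal, class-wise homoscedastic on the log
  scale) and the censoring treatment (lognormal CDF at the LOD) are
  package choices; the source does not state its conventions.
* The iTTC rests on generic assessment-factor distributions; nothing
  in the blood derivation is chemical-specific to TeA.
* Exposure screening treats spot plasma samples as steady-state
  concentrations.
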
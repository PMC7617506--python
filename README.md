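# teatk

Population toxicokinetics and biomonitoring-based risk screening for
**tenuazonic acid (TeA)**, an *Alternaria* mycotoxin that contaminates
cereals, tomatoes and infant foods.  The package is aimed at
toxicokinetic modellers and risk assessors who want to

1. fit a **multi-compartment population TK model** to single-bolus
   intervention-trial data (blood concentrations and per-void urinary
   masses, free and hydrolyzed-total) with a **hierarchical Bayesian**
   treatment of inter-individual variability,
2. derive a **probabilistic internal Threshold of Toxicological Concern
   (iTTC)** in blood and urine, and
3. screen **human biomonitoring (HBM) cohorts** for risk via hazard
   quotients and a nested Monte Carlo individual margin of exposure.

## The models

**Kinetics.** An oral bolus enters the GI tract and is completely
absorbed (first-order rate k_gutabs) into a central compartment of free
TeA (distribution volume Vd).  Free TeA is either excreted in urine
(rate k_u = k_ufrac·k_el) or conjugated to phase-II metabolites
(rate k_met = (1−k_ufrac)·k_el, with k_el = Cl_tot/Vd), which are in
turn excreted in urine (rate k_umet = Cl_met/Vd_met).  A fraction
F_gluc of the urinary metabolites is released by enzymatic hydrolysis,
so the "total" analyte is free TeA + glucuronides.  The cascade is
linear, solved in closed form, and cross-checked against a stiff ODE
integration.

**Population layer.** Each individual's log parameter vector is normal
around a population mean: parameters are lognormal(GM, GSD) across
subjects.  Measurement error is multiplicative lognormal per
observation class; values below the LOD contribute the lognormal CDF
(left-censoring).  Posterior sampling uses adaptive
Metropolis-within-Gibbs with dedicated ridge and translation moves;
convergence is judged by the split-chain Gelman–Rubin statistic
(R̂ ≤ 1.2).

**iTTC.**  iTTC = NOEL / (AF_PoD-NOAEL × AF_interTD × GSD_intraTD^z),
with every term a lognormal uncertainty distribution (WHO/IPCS
parameterization, z = 2.326 for 1% population incidence) combined by
Monte Carlo; the reported point value is the lower one-tailed 95%
confidence bound.  For urine the NOEL converts to a 24-h excretion via
Cl_tot·k_ufrac·24 and the intraspecies GSD mixes TK and TD
variability.

## Worked example

```python
import numpy as np
from teatk import PopTKModel, gen_trial, derive, TKParams

ds = gen_trial(seed=42)            # 10 subjects, 1500 ng/kg bolus, 48 h
res = PopTKModel(ds).fit(n_chains=4, n_iter=8000, seed=7)
print(res.rhat().max())            # 1.086  -> converged (<= 1.2)
print(res.summary().loc[["cl_tot", "vd", "t_half", "k_ufrac"],
                        ["gm_median", "gm_lo", "gm_hi"]].round(2))
```

```
parameter  gm_median  gm_lo  gm_hi
cl_tot          1.72   1.42   2.07
vd              5.07   3.98   6.45
t_half          2.05   1.52   2.77
k_ufrac         0.20   0.17   0.24
```

The 90% credible intervals bracket the generating population values
(Cl_tot 1.58 L/h·kg, Vd 4.35 L/kg, k_ufrac 0.212; half-life
ln2·Vd/Cl_tot ≈ 1.9 h).  Deriving the thresholds and screening a
urinary cohort:

```python
from teatk import derive_ittc_blood, derive_ittc_urine, CohortData, screen_cohort

blood = derive_ittc_blood(n_draws=100_000, seed=1)
print(blood.median, blood.prob_ittc)   # 10.6 nmol/L, 0.51 nmol/L

cohort = CohortData("demo", "urine_excretion",
                    [0.11, 0.09, 0.19, 0.06, 0.25, 0.12], "ug/kg-d")
row = screen_cohort(cohort, seed=5).table_row()
print(row["dose"]["median"], row["hq_ttc"]["median"])   # 0.54, 0.36
```

A dose of ~0.5 μg/kg-d and HQ_TTC well below 1 indicates no concern
for this (low-exposure) urinary cohort; plasma cohorts at ~0.3–0.9
ng/mL give HQs above 1.

There is also a CLI covering the whole pipeline:

```bash
teatk simulate --seed 7 --out trial/
teatk fit --trial trial/ --out fit/
teatk ittc --matrix both --seed 1 --out ittc/
teatk screen --cohorts cohorts.csv --out screen/
teatk report --fit fit/ --ittc ittc/ --screen screen/
```

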
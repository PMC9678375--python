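# ckdpipe

Rule-based chronic kidney disease (CKD) phenotyping, kidney-failure risk
scoring and nephrology-referral classification over longitudinal primary-care
laboratory data — plus a synthetic cohort generator so the whole pipeline can
be exercised end-to-end with known ground truth.

The package is aimed at epidemiologists and health-data scientists studying
how the 2021 change in UK nephrology referral guidance — replacing the fixed
eGFR <30 mL/min/1.73 m² referral threshold with the Kidney Failure Risk
Equation (KFRE) — and the switch to race-free eGFR reporting reshape CKD
diagnosis, monitoring and referral in routine primary-care records.

## What it computes

**eGFR equations.** Serum creatinine (µmol/L, converted internally with
1 mg/dL = 88.4 µmol/L) is scored under three equations:

- MDRD (4-variable, IDMS-traceable):
  `eGFR = 175 · Scr^−1.154 · age^−0.203 · 0.742[female] · 1.212[Black]`
- CKD-EPI 2009:
  `eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female] · 1.159[Black]`
- CKD-EPI 2021 (race-free):
  `eGFR = 142 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.200 · 0.9938^age · 1.012[female]`

with sex-specific κ (0.7 female / 0.9 male) and α.  All coefficients live in
a checksummed JSON data file (`src/ckdpipe/data/equation_coefficients.json`),
and every forward map has an exact closed-form inverse
(`invert_egfr_to_creatinine`), which the generator uses to emit creatinine
from latent eGFR trajectories.

**KFRE.** The 4-variable 5-year Kidney Failure Risk Equation,

```
risk = 1 − S0 ^ exp( −0.2201·(age/10 − 7.036) + 0.2467·(male − 0.5642)
                     −0.5567·(eGFR/5 − 7.222) + 0.4510·(ln ACRmg/g − 5.137) )
```

with uACR converted from UK units (mg/mmol → mg/g, ×8.84) and two baseline
survivals: North-American (S0 = 0.8996) and the non-North-American
recalibration (S0 = 0.9365, the default for UK cohorts).  A patient with no
uACR has *no computable risk* — represented explicitly, never as zero.

**Longitudinal phenotyping.** Guideline-style temporal rules over irregular
eGFR series: confirmed sustained threshold crossings (two values ≥91 days
apart with no intervening recovery), prevalent stage G3A/G3B per calendar
year (two values 30–59 ≥3 months apart, no later value >60), accelerated
decline (fall ≥25% or ≥15 mL/min/1.73 m² within 12 months, sustained ≥3
months), and incident CKD G3–5 / G4–5 onset dates.

**Referral categories.** Per patient-year, the three mutually exclusive
NICE-2021 referral routes: *accelerated decline or albuminuria*
(uACR ≥70 mg/mmol), *sustained eGFR <30 only*, and *KFRE >5% only* — with
the two published sensitivity variants (200 mg/mmol for diabetic patients;
30 mg/mmol for everyone as a haematuria proxy), nephrology-follow-up
exclusion, and the highest in-year KFRE per patient.

**Monitoring and equation impact.** Annual uACR testing rates among the
prevalent G3A/G3B cohort (stratified by age, sex, eGFR band, diabetes,
hypertension and CKD coding, with χ²/ANOVA group comparisons), and
reclassification summaries quantifying what changes when a laboratory
switches eGFR equations (counts, fold change, gained/lost patients, the
per-patient eGFR shift as median with interquartile interval, strata).

## Worked example

```python
>>> from ckdpipe import egfr_mdrd, egfr_ckdepi_2021, kfre_5yr
>>> egfr_mdrd(150, 74, "female")            # Scr 150 µmol/L, age 74
29.4
>>> egfr_ckdepi_2021(150, 74, "female")     # same sample, race-free refit
31.3
>>> kfre_5yr(74, "female", 33.4, acr_mg_mmol=80)
0.1267
```

The same creatinine maps to stage G4 under MDRD but G3B under CKD-EPI 2021 —
the reclassification the `impact` module measures at cohort scale — and with
uACR 80 mg/mmol this patient's 5-year kidney-failure risk is 12.7%, well
above the 5% referral threshold.

A full synthetic run:

```python
>>> from ckdpipe import CohortConfig, generate_cohort, run_pipeline
>>> cohort = generate_cohort(CohortConfig(n_patients=2000, seed=42))
>>> result = run_pipeline(cohort.labs, cohort.patients)
>>> result.prevalence.head(3).round(1)
   year  n_prevalent_g3  denominator   pct
0  2013             149         1421  10.5
1  2014             170         1393  12.2
2  2015             177         1381  12.8
```

Prevalence here is the share of patients with a confirmed G3A/G3B pattern
among those with at least one in-year creatinine who survived the year.
`result.testing` gives the annual uACR testing rate in that cohort (31–44%
in this run), `result.category_counts` the per-year referral categories
(e.g. 2019: 8 decline-or-albuminuria, 2 eGFR<30-only, 5 KFRE-only out of 121
counted, with 81 untestable for KFRE for want of a uACR), and
`result.reclassification["g3_5"]` the MDRD→CKD-EPI-2021 switch summary
(median per-patient eGFR gain 1.9 mL/min/1.73 m², IQI 1.3–2.7, in this
stable-G3-dominated cohort).

The same stages are available from a shell:

```bash
ckdpipe simulate --out sim/ --seed 4 --n-patients 5000
ckdpipe run-all --out report/ --seed 4 --labs sim/labs.csv --patients sim/patients.csv
ckdpipe score table.csv --out scored.csv --equation ckdepi2021
ckdpipe refer sim/labs.csv sim/patients.csv --out refer/ --variant diabetes_200
ckdpipe impact sim/labs.csv sim/patients.csv --out impact.json --from mdrd --to ckdepi2021
```

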
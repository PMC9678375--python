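# Methods

This note documents the models and procedures `ckdpipe` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Equations and units

Creatinine is held in µmol/L (UK laboratory reporting) and converted to
mg/dL (factor 88.4) only at the equation boundary; uACR is held in mg/mmol
and converted to mg/g (factor 8.84) only inside the KFRE.  The three eGFR
equations (MDRD 4-variable IDMS, CKD-EPI 2009, CKD-EPI 2021) and the
4-variable 5-year KFRE are loaded from a versioned JSON data file whose
payload is SHA-256-checksummed at load time, so a coefficient edit is always
an auditable data change, never a silent code change.  The KFRE ships both
published calibrations; the non-North-American recalibrated baseline
survival (0.9365 at 5 years) is the default since the intended cohorts are
UK-based, with the North-American development value (0.8996) selectable by
configuration.  Sources do not state which calibration any given UK
laboratory panel would use, so it is configuration, not an assumption.

Inversion (`invert_egfr_to_creatinine`) is analytic: each forward map is a
strict power law in creatinine (two-branch for the CKD-EPI pair, with the
branch identified by comparing the target to the value at the knot κ), so
the inverse is closed-form and round-trips at machine precision — the
contract is a relative error below 1e−9, and a Brent root-finder cross-check
sits in the test suite.  Targets outside (1, 200) mL/min/1.73 m² are
rejected.

A missing or zero uACR makes the KFRE *not computable*, a first-class state
distinct from low risk: it drives the "untestable" denominators in the
referral reporting.  An optional detection-limit floor was considered and
rejected — inventing albuminuria for untested patients would silently move
patients between referral categories.

## Temporal rules

"Three months" is operationalised as ≥91 days everywhere (the conventional
quarter-year), configurable via `GuidelineThresholds`.  All rules use data
truncated at 31 December of the year under assessment; history may inform a
rule but index and confirming events must fall in-year.  Consequences and
tie-breaks:

- **Sustained crossing.**  A start value below threshold is confirmed by a
  later below-threshold value ≥91 days on, with no intervening value
  *above* the threshold; a value exactly at the threshold neither confirms
  nor breaks.  After a break, a later pair can still qualify.
- **Prevalent G3A/G3B.**  Two values in [30, 60) ≥91 days apart, with no
  value >60 after the start of the latest qualifying pair: a later normal
  value "resolves" the stage and a new pair re-establishes it, which keeps
  per-year prevalence well defined.  A patient whose sustained crossing
  below 30 began in an *earlier* year has progressed to G4–5 and is
  excluded; one who crosses below 30 during the year remains in that year's
  G3 cohort — they are precisely the in-year "eGFR <30 only" referrals —
  and leaves it the following year.  (Treating any pre-year-end crossing as
  exclusion would make that referral category structurally empty.)
- **Accelerated decline.**  A pair (i, j) within 365 days qualifies when
  v(j) ≤ max(v(i)·0.75, v(i) − 15); the qualifying level derived from the
  index value is also the sustain level: no rebound above it before a
  confirming value ≥91 days after j.  Reading the sustain threshold as the
  qualifying level (rather than, say, the stage boundary) makes the rule
  self-contained in the pair that triggered it.
- **Calendar censoring.**  A decline whose confirming value falls in
  January of the following year is not flagged in either year; the same
  left-censoring affects a calendar-year analysis of real records.
- **Duplicates.**  The last value per patient-day wins (lab-report
  supersession).
- Age enters every eGFR at the sample date (not frozen at baseline), since
  follow-up spans eight years; the guideline logic applies to adults only
  and under-18 samples are dropped at scoring.

## Referral logic

Flags per patient-year among the prevalent G3A/G3B cohort: accelerated
decline (index in-year), albuminuria (any in-year uACR at/above the
variant's threshold: 70 mg/mmol; 200 for diabetic patients in the
`diabetes_200` variant; 30 for everyone in the `haematuria_30` variant),
sustained eGFR <30 with in-year onset, and KFRE >5%.  The mutually
exclusive category follows the guideline's "only" wording: decline-or-
albuminuria ≻ eGFR<30-only ≻ KFRE-only.  For the KFRE, each in-year uACR is
paired with the nearest-in-time eGFR within ±182 days (ties broken toward
the same-or-earlier value, the result a GP would have had in hand) and the
highest risk across pairs is used — mirroring action on an elevated result.
The ±182-day window is configurable; it is the widest gap over which a GP
would plausibly treat the pair as contemporaneous.  Nephrology-followed
patients are discounted from category counts but their flags are computed
and exported, and the KFRE>5%-among-tested denominator deliberately includes
them.  Group comparisons (age, sex) use one-way ANOVA and χ² without
continuity correction (so identical groups give a statistic of exactly 0).

## Synthetic cohorts

The longitudinal generator emulates an eight-year (2013–2020) primary-care
laboratory extract.  Five latent piecewise-linear eGFR archetypes: healthy
(flat, 75–100), stable G3 (35–55, slope −0.5 ± 0.3 /yr), slow progressor
(35–45, −2 ± 0.5 /yr), accelerated decliner (one year whose fall exceeds
max(25% of start, 15), onset uniform over follow-up), and high-albuminuria
G3 (stable G3 with uACR lognormal, median 100 mg/mmol).  Default mix
0.90 / 0.055 / 0.015 / 0.010 / 0.020, giving ~8–10% prevalent G3A/G3B among
tested patients — the order of magnitude seen in primary care.  Within the
G3 band the baseline is mildly age-correlated (older patients sit higher):
community-cohort G3A in the very old is predominantly age-related nephron
loss, while younger in-band patients tend to carry intrinsic progressive
disease at lower eGFR.  This composition — not any age term in the
equations — is what makes an equation switch de-classify predominantly
older patients, and it is the package's own modelling choice.

Demographic marginals are Table-1-like for a UK cohort: 55% female,
ethnicity mix 94.7/1.8/2.4/0.2/0.9% (white/black/asian/mixed/other), G3
classes centred at age 77 (SD 8), healthy at 52 (SD 16); diabetes 14%/30%
(healthy/G3), hypertension 26%/62%, CKD coding 50% of G3 patients,
nephrology follow-up 5%.  Visits are Poisson per year (1.2/yr healthy,
4–5/yr G3 classes) with within-year day fractions Beta(1, 1.4) — clustered
toward the year start to stress calendar-edge logic.  Deaths follow an
annual hazard by attained age (0.4%/1%/3%/8%/18% for <60/60s/70s/80s/90+).
uACR testing is an annual Bernoulli keyed by (diabetes, CKD-coded):
0.65/0.45/0.35/0.15 — reproducing the real gradient of testing by coding
and diabetes, with overall rates in the 25–45% range.

Observed creatinine = latent eGFR inverted through the configured target
equation (MDRD by default, matching the study era's laboratory reporting)
times mean-one lognormal noise (CV 0.06, assay plus biological variability).
With `noise_cv=0` the observed table equals the latent table exactly, which
gives the key end-to-end identity: the pipeline run on observed data must
reproduce, bit for bit, the run on ground truth.  Ground-truth flags are
defined by applying the same guideline rules to the noise-free values at
the actual visit dates (plus analytic latent crossing dates), so truth and
pipeline share the visit process and differ only by measurement noise.  At
CV 0.06 a calibration run gave ~97–98% per-patient-year category agreement;
the recorded acceptance floor is 95%.

A separate cross-sectional generator (`generate_crosssection`) draws flat
latent eGFR uniformly over 25–75 — deliberately covering the 55–60 boundary
zone that the archetype classes avoid — for the equation-switch analyses,
with the same within-band age gradient.

**What the synthetic cohorts do not show.**  No ethnicity-specific biology
is simulated (ethnicity matters only through the equations), so
KFRE-by-ethnicity tables on synthetic data are structurally flat; no
laboratory value quantisation (real creatinine is reported in integer
µmol/L — rounding would break the noiseless identity and is deliberately
omitted); no Read-code structure, no within-patient testing-behaviour
correlation, and only a crude per-year visit-rate multiplier for
pandemic-era suppression.  Passing tests therefore establish the *logic* of
the pipeline under known truth, not the cohort-specific counts of any real
population — which is also why reported percentages (e.g. category shares)
differ in level from published real-data figures while matching them in
structure and direction.

## Problem sizes and determinism

Tests and the acceptance script use 2,000 patients for the noiseless
identity, 20,000 for planted-proportion recovery (three binomial standard
errors, two-sample form since the plant is itself an empirical proportion
of the ground-truth run), 2,500–10,000 for the cross-sectional
reclassification cohorts, and exhaustive rule-vs-brute-force enumeration
over all series of length ≤5 on a 6-value × 3-gap grid (~0.67M series)
plus 20,000 random longer series — sizes at which every binomial check has
comfortable power while a full run stays in the tens of seconds.  All
randomness flows from a single `numpy` Generator seeded from the run seed;
identical seeds give byte-identical tables, reports and JSON.

## Known limitations

- The prevalence "resolution" rule (any later value >60 after the latest
  qualifying pair) is one of several defensible readings; the alternative
  (no resolution) can be obtained by setting `g3_high` and re-deriving, but
  is not currently a switch.
- KFRE pairing uses one eGFR per uACR (nearest in window); pairing every
  in-year combination would be monotonically more conservative and is
  intentionally not the default.
- The stage table covers G3–G5 bands only; G1/G2 and formal KDIGO
  albuminuria A-categories are out of scope, as are dialysis/transplant
  event capture and cystatin-C or paediatric equations.
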
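"""Synthetic longitudinal primary-care cohorts with known ground truth.

The generator emulates the structure of a UK primary-care laboratory
extract — irregular creatinine test dates over a span of calendar years,
sparse class-dependent uACR testing, Table-1-like demographic marginals —
without any ethnicity-specific trajectory biology (a documented limitation:
ethnicity matters only to the equation-switching analyses).

Each patient carries a latent piecewise-linear eGFR trajectory drawn from
one of five archetypes:

* ``healthy`` — flat baseline 75–100;
* ``stable_g3`` — baseline 35–55, slope −0.5 ± 0.3 /yr;
* ``slow_progressor`` — baseline 35–45, slope −2 ± 0.5 /yr, drifting across
  the G4 boundary without ever meeting the accelerated-decline rule;
* ``accelerated_decliner`` — one year in which the fall exceeds
  max(25% of start, 15 mL/min/1.73 m²);
* ``high_albuminuria_g3`` — a stable G3 trajectory with uACR centred at
  100 mg/mmol.

Within the G3 band the baseline is mildly age-correlated (older patients sit
higher in the band): community G3A in the very old is predominantly
age-related nephron loss, while younger patients in the band tend to carry
intrinsic progressive disease at lower eGFR.

Observed creatinine is the latent eGFR inverted through the configured
target equation and multiplied by mean-one lognormal noise; ``noise_cv=0``
reproduces the latent values exactly, which is the key end-to-end identity
used in testing.  Ground truth (class, latent band-crossing dates, and a
noise-free copy of the laboratory table) is returned alongside the data so
every pipeline stage can be checked against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .equations import EQUATIONS, invert_egfr_to_creatinine
from .phenotyping import year_start_day

__all__ = [
    "CLASSES",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_crosssection",
]

CLASSES = (
    "healthy",
    "stable_g3",
    "slow_progressor",
    "accelerated_decliner",
    "high_albuminuria_g3",
)
G3_CLASSES = CLASSES[1:]

DAYS_PER_YEAR = 365.25


def _class_map(default: dict) -> dict:
    return dict(default)


class CohortConfig(BaseModel):
    """Generator configuration; identical seed ⇒ bit-identical cohort."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = 20_000
    seed: int = 0
    start_year: int = 2013
    end_year: int = 2020
    class_mix: dict[str, float] = {
        "healthy": 0.900,
        "stable_g3": 0.055,
        "slow_progressor": 0.015,
        "accelerated_decliner": 0.010,
        "high_albuminuria_g3": 0.020,
    }
    visit_rate: dict[str, float] = {
        "healthy": 1.2,
        "stable_g3": 4.0,
        "slow_progressor": 4.0,
        "accelerated_decliner": 5.0,
        "high_albuminuria_g3": 4.0,
    }
    #: annual Bernoulli probability of ≥1 uACR test, by (diabetes, ckd_coded)
    acr_testing_prob: dict[str, float] = {
        "diabetic_coded": 0.65,
        "diabetic_uncoded": 0.45,
        "nondiabetic_coded": 0.35,
        "nondiabetic_uncoded": 0.15,
    }
    extra_acr_prob: float = 0.25
    noise_cv: float = 0.06
    female_fraction: float = 0.55
    ethnicity_mix: dict[str, float] = {
        "white": 0.947,
        "black": 0.018,
        "asian": 0.024,
        "mixed": 0.002,
        "other": 0.009,
    }
    age_mean: dict[str, float] = _class_map(
        {"healthy": 52.0, "stable_g3": 77.0, "slow_progressor": 77.0,
         "accelerated_decliner": 77.0, "high_albuminuria_g3": 77.0}
    )
    age_sd: dict[str, float] = _class_map(
        {"healthy": 16.0, "stable_g3": 8.0, "slow_progressor": 8.0,
         "accelerated_decliner": 8.0, "high_albuminuria_g3": 8.0}
    )
    diabetes_prob: dict[str, float] = _class_map(
        {"healthy": 0.14, "stable_g3": 0.30, "slow_progressor": 0.30,
         "accelerated_decliner": 0.30, "high_albuminuria_g3": 0.30}
    )
    hypertension_prob: dict[str, float] = _class_map(
        {"healthy": 0.26, "stable_g3": 0.62, "slow_progressor": 0.62,
         "accelerated_decliner": 0.62, "high_albuminuria_g3": 0.62}
    )
    ckd_coded_prob: dict[str, float] = _class_map(
        {"healthy": 0.0, "stable_g3": 0.50, "slow_progressor": 0.50,
         "accelerated_decliner": 0.50, "high_albuminuria_g3": 0.50}
    )
    nephrology_prob: dict[str, float] = _class_map(
        {"healthy": 0.0, "stable_g3": 0.05, "slow_progressor": 0.05,
         "accelerated_decliner": 0.05, "high_albuminuria_g3": 0.05}
    )
    acr_median_mg_mmol: dict[str, float] = _class_map(
        {"healthy": 0.8, "stable_g3": 5.0, "slow_progressor": 10.0,
         "accelerated_decliner": 15.0, "high_albuminuria_g3": 100.0}
    )
    acr_sigma: dict[str, float] = _class_map(
        {"healthy": 0.8, "stable_g3": 0.9, "slow_progressor": 0.9,
         "accelerated_decliner": 0.9, "high_albuminuria_g3": 0.5}
    )
    #: (upper age bound, annual death hazard); last bound is open-ended
    annual_death_hazard: tuple[tuple[float, float], ...] = (
        (60.0, 0.004),
        (70.0, 0.010),
        (80.0, 0.030),
        (90.0, 0.080),
        (math.inf, 0.180),
    )
    target_equation: str = "mdrd"
    #: per-year multiplier on visit rates (e.g. pandemic-era suppression)
    visit_rate_year_multiplier: dict[int, float] = {}
    #: Beta(a, b) law for the within-year day fraction (clusters visits early)
    visit_day_beta: tuple[float, float] = (1.0, 1.4)
    age_baseline_slope: float = 0.03  # within-band age gradient of the G3 baseline

    @model_validator(mode="after")
    def _check(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be ≥ start_year")
        if set(self.class_mix) != set(CLASSES):
            raise ValueError(f"class_mix must have exactly the keys {CLASSES}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for name in ("class_mix", "acr_testing_prob", "ethnicity_mix", "diabetes_prob",
                     "hypertension_prob", "ckd_coded_prob", "nephrology_prob"):
            for key, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{key}] must be a probability, got {p}")
        if abs(sum(self.ethnicity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("ethnicity_mix must sum to 1")
        if any(r < 0 for r in self.visit_rate.values()):
            raise ValueError("visit rates cannot be negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv cannot be negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be a probability")
        if self.target_equation not in EQUATIONS:
            raise ValueError(f"target_equation must be one of {EQUATIONS}")
        return self

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass
class GroundTruth:
    """What was planted: classes, latent crossings, and noise-free labs.

    ``latent_labs`` is the laboratory table with the noise multiplier
    removed; running the pipeline on it yields the per-year ground-truth
    stage and referral flags, consistent with the latent trajectory by
    construction.
    """

    classes: pd.DataFrame  # patient_id, true_class, latent_g3_onset, latent_g4_onset
    latent_labs: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: pd.DataFrame
    labs: pd.DataFrame
    truth: GroundTruth


def generate_crosssection(
    n_patients: int,
    seed: int,
    *,
    ethnicity: str = "white",
    equation: str = "mdrd",
    egfr_range: tuple[float, float] = (25.0, 75.0),
    noise_cv: float = 0.04,
    start_year: int = 2018,
    n_visits: int = 4,
    female_fraction: float = 0.55,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-sectional cohort spanning the CKD band, for reclassification studies.

    Each patient has a flat latent eGFR drawn uniformly over ``egfr_range``
    and inverted to creatinine under ``equation``, observed at ``n_visits``
    dates across ~18 months with multiplicative noise — enough to satisfy
    the confirmed two-value rule.  Age rises with in-band eGFR (mild G3A in
    community cohorts is predominantly age-related nephron loss in the very
    old, while younger patients sitting deeper in the band tend to carry
    intrinsic progressive disease), which is what drives the older-female
    enrichment among patients de-classified by an equation switch.

    Returns (patients, labs) tables directly usable by the pipeline.
    """
    rng = np.random.default_rng(seed)
    egfr0 = rng.uniform(*egfr_range, size=n_patients)
    age = np.clip(58.0 + 0.38 * (egfr0 - egfr_range[0]) + rng.normal(0.0, 9.0, n_patients), 18.5, 96.0)
    female = rng.random(n_patients) < female_fraction
    sex = np.where(female, "female", "male").astype(object)
    start_day = year_start_day(start_year)
    dob_day = start_day - np.round(age * DAYS_PER_YEAR).astype(np.int64)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    pid_width = len(str(n_patients))
    pids = np.array([f"X{i:0{pid_width}d}" for i in range(1, n_patients + 1)], dtype=object)

    rows_pid, rows_day, rows_creat = [], [], []
    black = ethnicity == "black"
    for i in range(n_patients):
        days = start_day + np.sort(rng.choice(540, size=n_visits, replace=False))
        age_at = (days - dob_day[i]) / DAYS_PER_YEAR
        creat = np.atleast_1d(
            invert_egfr_to_creatinine(
                np.full(n_visits, egfr0[i]), age_at, str(sex[i]), equation,
                black=black, use_ethnicity=black,
            )
        )
        if sigma > 0:
            creat = creat * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_visits))
        rows_pid.extend([pids[i]] * n_visits)
        rows_day.append(days)
        rows_creat.append(creat)

    labs = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "date": pd.to_datetime(np.concatenate(rows_day), unit="D", origin="unix"),
            "creatinine_umol_l": np.concatenate(rows_creat),
            "acr_mg_mmol": np.nan,
        }
    ).sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "dob": pd.to_datetime(dob_day, unit="D", origin="unix"),
            "sex": sex,
            "ethnicity": ethnicity,
            "diabetes": False,
            "hypertension": False,
            "ckd_coded": False,
            "nephrology_followup": False,
            "death_date": pd.NaT,
        }
    )
    return patients, labs


def _latent_crossing(knots_t: np.ndarray, knots_g: np.ndarray, threshold: float) -> float | None:
    """First time (years from study start) the latent trajectory falls below threshold."""
    if knots_g[0] < threshold:
        return float(knots_t[0])
    for a in range(len(knots_t) - 1):
        g0, g1 = knots_g[a], knots_g[a + 1]
        if g1 < threshold <= g0:
            frac = (g0 - threshold) / (g0 - g1)
            return float(knots_t[a] + frac * (knots_t[a + 1] - knots_t[a]))
    return None


def _trajectory_knots(cls: str, age: float, span: float, cfg: CohortConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    if cls == "healthy":
        g0 = rng.uniform(75.0, 100.0)
        return np.array([0.0, span]), np.array([g0, g0])
    if cls in ("stable_g3", "high_albuminuria_g3"):
        q = float(np.clip(0.5 + cfg.age_baseline_slope * (age - 77.0) + rng.normal(0.0, 0.22), 0.0, 1.0))
        b = 35.0 + 20.0 * q
        slope = rng.normal(-0.5, 0.3)
        return np.array([0.0, span]), np.array([b, b + slope * span])
    if cls == "slow_progressor":
        b = rng.uniform(35.0, 45.0)
        slope = min(rng.normal(-2.0, 0.5), -0.5)
        return np.array([0.0, span]), np.array([b, b + slope * span])
    if cls == "accelerated_decliner":
        b = rng.uniform(45.0, 65.0)
        t0 = rng.uniform(0.5, span - 1.5)
        g_t0 = b - 0.5 * t0
        drop = max(0.25 * g_t0, 15.0) * rng.uniform(1.15, 1.45)
        g_after = g_t0 - drop
        g_end = g_after - 1.0 * (span - t0 - 1.0)
        return (
            np.array([0.0, t0, t0 + 1.0, span]),
            np.array([b, g_t0, g_after, g_end]),
        )
    raise ValueError(f"unknown class {cls!r}")


def _eval_trajectory(knots_t, knots_g, t_years) -> np.ndarray:
    return np.maximum(np.interp(t_years, knots_t, knots_g), 6.0)


def _acr_key(diabetes: bool, coded: bool) -> str:
    return ("diabetic_" if diabetes else "nondiabetic_") + ("coded" if coded else "uncoded")


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate (patients, labs, ground truth) tables for one synthetic cohort.

    Deterministic under the config seed: two calls with equal configs return
    byte-identical tables.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    span = float(cfg.n_years)
    start_day = year_start_day(cfg.start_year)

    class_names = np.array(CLASSES)
    mix = np.array([cfg.class_mix[c] for c in CLASSES])
    cls = class_names[rng.choice(len(CLASSES), size=n, p=mix)]
    female = rng.random(n) < cfg.female_fraction
    sex = np.where(female, "female", "male").astype(object)
    eth_names = sorted(cfg.ethnicity_mix)
    eth_p = np.array([cfg.ethnicity_mix[e] for e in eth_names])
    ethnicity = np.array(eth_names, dtype=object)[rng.choice(len(eth_names), size=n, p=eth_p)]

    mean = np.array([cfg.age_mean[c] for c in cls])
    sd = np.array([cfg.age_sd[c] for c in cls])
    age_start = np.clip(rng.normal(mean, sd), 18.5, 96.0)
    dob_day = start_day - np.round(age_start * DAYS_PER_YEAR).astype(np.int64)

    def class_bernoulli(table):
        p = np.array([table[c] for c in cls])
        return rng.random(n) < p

    diabetes = class_bernoulli(cfg.diabetes_prob)
    hypertension = class_bernoulli(cfg.hypertension_prob)
    ckd_coded = class_bernoulli(cfg.ckd_coded_prob)
    nephrology = class_bernoulli(cfg.nephrology_prob)

    # trajectories (per patient, fixed order)
    knots = [_trajectory_knots(c, a, span, cfg, rng) for c, a in zip(cls, age_start)]

    # annual death hazard by attained age; death day uniform within the year
    death_day = np.full(n, -1, dtype=np.int64)  # -1 = alive at study end
    alive = np.ones(n, dtype=bool)
    bounds = [b for b, _ in cfg.annual_death_hazard]
    hazards = np.array([h for _, h in cfg.annual_death_hazard])
    for y in range(cfg.n_years):
        attained = age_start + y
        hz = hazards[np.searchsorted(bounds, attained, side="right")]
        dies = alive & (rng.random(n) < hz)
        offs = (rng.random(n) * 365.0).astype(np.int64)
        ys = year_start_day(cfg.start_year + y)
        death_day[dies] = ys + offs[dies]
        alive &= ~dies

    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0

    pid_width = len(str(n))
    pids = np.array([f"P{i:0{pid_width}d}" for i in range(1, n + 1)], dtype=object)

    lab_pid: list[str] = []
    lab_day: list[np.ndarray] = []
    lab_creat: list[np.ndarray] = []
    lab_latent_creat: list[np.ndarray] = []
    acr_pid: list[str] = []
    acr_day: list[int] = []
    acr_val: list[float] = []

    beta_a, beta_b = cfg.visit_day_beta
    for i in range(n):
        kt, kg = knots[i]
        d_day = death_day[i]
        days_i: list[int] = []
        for y in range(cfg.n_years):
            year = cfg.start_year + y
            ys = year_start_day(year)
            if d_day >= 0 and d_day < ys:
                break
            rate = cfg.visit_rate[cls[i]] * cfg.visit_rate_year_multiplier.get(year, 1.0)
            k = rng.poisson(rate)
            if k > 0:
                fracs = rng.beta(beta_a, beta_b, size=k)
                days = ys + np.floor(fracs * 365.0).astype(np.int64)
                if d_day >= 0:
                    days = days[days < d_day]
                days_i.extend(days.tolist())
            # uACR testing: annual Bernoulli by (diabetes, CKD-coded)
            p_test = cfg.acr_testing_prob[_acr_key(diabetes[i], ckd_coded[i])]
            if rng.random() < p_test:
                n_acr = 1 + (rng.random() < cfg.extra_acr_prob)
                a_days = ys + np.floor(rng.random(n_acr) * 365.0).astype(np.int64)
                if d_day >= 0:
                    a_days = a_days[a_days < d_day]
                vals = cfg.acr_median_mg_mmol[cls[i]] * np.exp(
                    rng.normal(0.0, cfg.acr_sigma[cls[i]], size=len(a_days))
                )
                for ad, av in zip(a_days, vals):
                    acr_pid.append(pids[i])
                    acr_day.append(int(ad))
                    acr_val.append(float(av))
        if not days_i:
            continue
        days_arr = np.unique(np.asarray(days_i, dtype=np.int64))
        t_years = (days_arr - start_day) / DAYS_PER_YEAR
        latent = _eval_trajectory(kt, kg, t_years)
        age_at = (days_arr - dob_day[i]) / DAYS_PER_YEAR
        latent_creat = np.atleast_1d(
            invert_egfr_to_creatinine(latent, age_at, str(sex[i]), cfg.target_equation)
        )
        if sigma > 0:
            mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(days_arr)))
        else:
            mult = np.ones(len(days_arr))
        lab_pid.extend([pids[i]] * len(days_arr))
        lab_day.append(days_arr)
        lab_creat.append(latent_creat * mult)
        lab_latent_creat.append(latent_creat)

    day_arr = np.concatenate(lab_day) if lab_day else np.array([], dtype=np.int64)
    creat_rows = pd.DataFrame(
        {
            "patient_id": lab_pid,
            "date": pd.to_datetime(day_arr, unit="D", origin="unix"),
            "creatinine_umol_l": np.concatenate(lab_creat) if lab_creat else [],
            "acr_mg_mmol": np.nan,
            "_latent_creatinine": np.concatenate(lab_latent_creat) if lab_latent_creat else [],
        }
    )
    acr_rows = pd.DataFrame(
        {
            "patient_id": acr_pid,
            "date": pd.to_datetime(np.asarray(acr_day, dtype=np.int64), unit="D", origin="unix"),
            "creatinine_umol_l": np.nan,
            "acr_mg_mmol": acr_val,
            "_latent_creatinine": np.nan,
        }
    )
    labs = pd.concat([creat_rows, acr_rows], ignore_index=True)
    labs = labs.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    latent_labs = labs.drop(columns=["creatinine_umol_l"]).rename(
        columns={"_latent_creatinine": "creatinine_umol_l"}
    )[["patient_id", "date", "creatinine_umol_l", "acr_mg_mmol"]]
    labs = labs[["patient_id", "date", "creatinine_umol_l", "acr_mg_mmol"]]

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "dob": pd.to_datetime(dob_day, unit="D", origin="unix"),
            "sex": sex,
            "ethnicity": ethnicity,
            "diabetes": diabetes,
            "hypertension": hypertension,
            "ckd_coded": ckd_coded,
            "nephrology_followup": nephrology,
            "death_date": pd.to_datetime(
                np.where(death_day >= 0, death_day, np.iinfo(np.int64).min),
                unit="D",
                origin="unix",
                errors="coerce",
            ),
        }
    )
    patients.loc[death_day < 0, "death_date"] = pd.NaT

    g3_onset, g4_onset = [], []
    for i in range(n):
        kt, kg = knots[i]
        for store, thr in ((g3_onset, 60.0), (g4_onset, 30.0)):
            x = _latent_crossing(kt, kg, thr)
            store.append(
                pd.NaT
                if x is None
                else pd.Timestamp(
                    pd.to_datetime(start_day + int(round(x * DAYS_PER_YEAR)), unit="D", origin="unix")
                )
            )
    classes = pd.DataFrame(
        {
            "patient_id": pids,
            "true_class": cls,
            "latent_g3_onset": g3_onset,
            "latent_g4_onset": g4_onset,
        }
    )
    return SyntheticCohort(
        config=cfg,
        patients=patients,
        labs=labs,
        truth=GroundTruth(classes=classes, latent_labs=latent_labs),
    )
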
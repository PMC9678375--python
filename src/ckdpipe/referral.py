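"""NICE-2021 style nephrology referral criteria per patient per calendar year.

Among patients with prevalent CKD stage G3A/G3B, four criterion flags are
evaluated for each calendar year:

* ``accel_decline`` — confirmed accelerated eGFR decline with index date in
  the year (evaluated on data through 31 December of the year);
* ``albuminuria`` — any in-year uACR at or above the variant's threshold
  (main: 70 mg/mmol; ``diabetes_200``: 200 mg/mmol for diabetic patients and
  70 otherwise; ``haematuria_30``: 30 mg/mmol for everyone, a proxy for the
  haematuria-accompanied referral route);
* ``egfr_lt30`` — a sustained crossing below 30 mL/min/1.73 m² with onset in
  the year;
* ``kfre_gt5`` — highest in-year 5-year KFRE above 5%, or *not computable*
  when the patient has no in-year uACR (never silently false: the share of
  untestable patients is itself a headline quantity).

The mutually exclusive referral category follows the guideline's "only"
wording: decline-or-albuminuria takes precedence, then sustained eGFR <30,
then KFRE.  Patients currently or previously under nephrology follow-up are
flagged so they can be discounted from referral counts while their raw flags
remain available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .equations import KfreParameters, kfre_5yr
from .phenotyping import (
    EgfrSeries,
    GuidelineThresholds,
    accelerated_decline_index_days,
    first_sustained_below,
    year_end_day,
    year_start_day,
)

__all__ = [
    "CATEGORIES",
    "VARIANTS",
    "ReferralFlags",
    "ReferralAssessment",
    "albuminuria_threshold",
    "criterion_flags",
    "max_kfre_in_year",
    "exclusive_category",
    "compare_groups",
]

CATEGORIES = ("decline_or_albuminuria", "egfr_lt30_only", "kfre_only", "none")
VARIANTS = ("main", "diabetes_200", "haematuria_30")


@dataclass(frozen=True)
class ReferralFlags:
    accel_decline: bool
    albuminuria: bool
    egfr_lt30: bool
    kfre_gt5: bool | None  # None ⇒ no in-year ACR, risk not computable


@dataclass(frozen=True)
class ReferralAssessment:
    patient_id: str
    year: int
    flags: ReferralFlags
    category: str
    kfre_untestable: bool
    max_kfre: float | None
    excluded_nephrology: bool


def albuminuria_threshold(
    variant: str, diabetes: bool, thresholds: GuidelineThresholds
) -> float:
    if variant == "main":
        return thresholds.albuminuria_referral
    if variant == "diabetes_200":
        return (
            thresholds.albuminuria_diabetes_sensitivity
            if diabetes
            else thresholds.albuminuria_referral
        )
    if variant == "haematuria_30":
        return thresholds.albuminuria_haematuria_sensitivity
    raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def _in_year(days, year: int) -> np.ndarray:
    days = np.asarray(days)
    return (days >= year_start_day(year)) & (days <= year_end_day(year))


def max_kfre_in_year(
    series: EgfrSeries,
    acr_days,
    acr_values,
    *,
    age_at_day,
    sex: str,
    year: int,
    params: KfreParameters | None = None,
    pair_window_days: int = 182,
) -> float | None:
    """Highest 5-year KFRE formed from in-year ACR values, or None.

    Each in-year ACR is paired with the nearest-in-time eGFR within
    ``pair_window_days`` (ties broken toward the same-or-earlier eGFR, the
    value a GP would have had in hand), and the maximum risk over the pairs
    is returned — mirroring practice of acting on the highest available
    result.  Returns None (risk not computable) when no in-year ACR exists,
    when every in-year ACR is 0/undetectable, or when no eGFR lies within
    the pairing window.  ``age_at_day`` maps an integer day to the patient's
    age in years on that day.
    """
    acr_days = np.asarray(acr_days)
    acr_values = np.asarray(acr_values, dtype=float)
    mask = _in_year(acr_days, year) & (acr_values > 0)
    if not mask.any() or len(series) == 0:
        return None
    best: float | None = None
    for a_day, a_val in zip(acr_days[mask], acr_values[mask]):
        delta = series.days - a_day
        within = np.abs(delta) <= pair_window_days
        if not within.any():
            continue
        cand = np.nonzero(within)[0]
        dist = np.abs(delta[cand])
        # prefer same-or-earlier eGFR on distance ties
        order = np.lexsort((delta[cand] > 0, dist))
        idx = cand[order[0]]
        risk = kfre_5yr(
            age_at_day(int(series.days[idx])),
            sex,
            float(series.values[idx]),
            acr_mg_mmol=float(a_val),
            params=params,
        )
        if best is None or risk > best:
            best = risk
    return best


def criterion_flags(
    series: EgfrSeries,
    acr_days,
    acr_values,
    *,
    year: int,
    diabetes: bool,
    sex: str,
    age_at_day,
    thresholds: GuidelineThresholds | None = None,
    params: KfreParameters | None = None,
    variant: str = "main",
    pair_window_days: int = 182,
) -> tuple[ReferralFlags, float | None]:
    """Per-year referral criterion flags for one prevalent-G3A/G3B patient.

    History before the year may inform the rules, but the index/confirming
    events must fall in-year and only data through 31 December are used.
    Returns the flags and the highest computable in-year KFRE.
    """
    t = thresholds or GuidelineThresholds()
    s = series.truncated(year_end_day(year))

    accel_days = accelerated_decline_index_days(s.days, s.values, t)
    accel = any(_in_year(np.asarray(accel_days), year)) if accel_days else False

    thr = albuminuria_threshold(variant, diabetes, t)
    acr_days = np.asarray(acr_days)
    acr_values = np.asarray(acr_values, dtype=float)
    in_year_acr = _in_year(acr_days, year)
    albuminuria = bool(np.any(acr_values[in_year_acr] >= thr))

    onset_idx = first_sustained_below(s.days, s.values, t.g3_low, t.sustain_days)
    egfr_lt30 = onset_idx is not None and bool(_in_year(s.days[onset_idx], year))

    risk = max_kfre_in_year(
        s,
        acr_days,
        acr_values,
        age_at_day=age_at_day,
        sex=sex,
        year=year,
        params=params,
        pair_window_days=pair_window_days,
    )
    kfre_gt5 = None if risk is None else bool(risk > t.kfre_referral)
    return ReferralFlags(accel, albuminuria, egfr_lt30, kfre_gt5), risk


def exclusive_category(flags: ReferralFlags) -> tuple[str, bool]:
    """Mutually exclusive referral category plus an 'untestable' annotation.

    Precedence encodes the guideline's "only" wording.  A not-computable
    KFRE reached at the last step yields ("none", True): the patient could
    not be risk-assessed for want of an ACR, which is distinct from a
    computed low risk.
    """
    if flags.accel_decline or flags.albuminuria:
        return "decline_or_albuminuria", False
    if flags.egfr_lt30:
        return "egfr_lt30_only", False
    if flags.kfre_gt5 is None:
        return "none", True
    return ("kfre_only" if flags.kfre_gt5 else "none"), False


def compare_groups(ages_a, ages_b, female_a, female_b) -> dict:
    """Two-group comparison: ANOVA on age, chi-square on sex, medians/IQI.

    ``female_*`` are boolean arrays.  With a group of fewer than two members
    only the descriptive summaries are reported (test entries are None).
    The chi-square is computed without continuity correction so identical
    groups give a statistic of exactly 0 (p = 1).
    """
    ages_a = np.asarray(ages_a, dtype=float)
    ages_b = np.asarray(ages_b, dtype=float)
    female_a = np.asarray(female_a, dtype=bool)
    female_b = np.asarray(female_b, dtype=bool)

    def describe(ages, female):
        return {
            "n": int(len(ages)),
            "median_age": float(np.median(ages)) if len(ages) else None,
            "age_iqi": (
                tuple(np.percentile(ages, [25, 75]).tolist()) if len(ages) else None
            ),
            "pct_female": float(100.0 * female.mean()) if len(female) else None,
        }

    out = {"group_a": describe(ages_a, female_a), "group_b": describe(ages_b, female_b)}
    if len(ages_a) < 2 or len(ages_b) < 2:
        out.update(anova_f=None, anova_p=None, chi2_stat=None, chi2_p=None)
        return out
    f_stat, f_p = stats.f_oneway(ages_a, ages_b)
    table = np.array(
        [
            [int(female_a.sum()), int((~female_a).sum())],
            [int(female_b.sum()), int((~female_b).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any():
        chi2, chi_p = 0.0, 1.0
    else:
        chi2, chi_p, _, _ = stats.chi2_contingency(table, correction=False)
    out.update(
        anova_f=float(f_stat), anova_p=float(f_p), chi2_stat=float(chi2), chi2_p=float(chi_p)
    )
    return out
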
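"""Rule-based longitudinal CKD phenotyping over irregular eGFR series.

The kernels operate on a per-patient series of (day, eGFR) pairs with
strictly increasing days (integer days since 1970-01-01) and implement the
guideline-style temporal rules:

* sustained threshold crossing — the earliest value below a threshold that is
  confirmed by a later below-threshold value at least ``sustain_days`` later,
  with no intervening value rising above the threshold;
* prevalent stage G3A/G3B in a calendar year — two values in the 30–59 band
  at least ``confirm_gap_days`` apart, no later value above 60 after the
  start of the latest qualifying pair, and no confirmed sustained crossing
  below 30 (those patients are G4–5, not G3);
* accelerated decline — a fall of ≥25% or ≥15 mL/min/1.73 m² within 12
  months, sustained for ≥3 months with no rebound above the qualifying level;
* incident CKD onset for bands G3–5 (eGFR <60) and G4–5 (eGFR <30).

"Three months" is operationalised as 91 days throughout, applied as ≥, and is
configurable via :class:`GuidelineThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "GuidelineThresholds",
    "EgfrSeries",
    "first_sustained_below",
    "first_sustained_below_date",
    "prevalent_g3_in_year",
    "accelerated_decline",
    "accelerated_decline_index_days",
    "incident_ckd_onset",
    "year_end_day",
    "year_start_day",
    "day_to_date",
]

EPOCH = np.datetime64("1970-01-01", "D")


def year_start_day(year: int) -> int:
    return int(np.datetime64(f"{year}-01-01", "D").astype(int))


def year_end_day(year: int) -> int:
    return int(np.datetime64(f"{year}-12-31", "D").astype(int))


def day_to_date(day: int | None):
    """Integer day offset → numpy date (or None)."""
    if day is None:
        return None
    return EPOCH + int(day)


class GuidelineThresholds(BaseModel):
    """Every numeric threshold of the guideline logic, configurable.

    Defaults encode the NICE-2021 style criteria: stage band 30–60
    mL/min/1.73 m², 91-day confirmation/sustain windows, accelerated decline
    of ≥25% relative or ≥15 mL/min/1.73 m² absolute within 365 days,
    albuminuria referral at uACR 70 mg/mmol (200 for the diabetes sensitivity
    analysis, 30 for the haematuria-proxy sensitivity analysis) and a 5-year
    KFRE referral threshold of 5%.
    """

    model_config = ConfigDict(frozen=True)

    g3_low: float = 30.0
    g3_high: float = 60.0
    confirm_gap_days: int = 91
    sustain_days: int = 91
    decline_rel: float = 0.25
    decline_abs: float = 15.0
    decline_window_days: int = 365
    albuminuria_referral: float = 70.0
    albuminuria_diabetes_sensitivity: float = 200.0
    albuminuria_haematuria_sensitivity: float = 30.0
    kfre_referral: float = 0.05

    @model_validator(mode="after")
    def _check(self):
        for name, value in self.model_dump().items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")
        if self.g3_low >= self.g3_high:
            raise ValueError("g3_low must be below g3_high")
        if not self.decline_rel < 1:
            raise ValueError("decline_rel is a fraction in (0, 1)")
        return self


@dataclass
class EgfrSeries:
    """Dated eGFR values for one patient under a named equation.

    ``days`` are integer days since 1970-01-01, strictly increasing;
    duplicate same-day records must already have been resolved upstream
    (the reader keeps the last value per patient-day).
    """

    patient_id: str
    equation: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have matching shape")
        if len(self.days) > 1 and not np.all(np.diff(self.days) > 0):
            raise ValueError("series days must be strictly increasing")

    def __len__(self) -> int:
        return len(self.days)

    @property
    def dates(self) -> np.ndarray:
        return EPOCH + self.days

    def truncated(self, last_day: int) -> "EgfrSeries":
        """Sub-series of values dated on or before ``last_day``."""
        n = int(np.searchsorted(self.days, last_day, side="right"))
        return EgfrSeries(self.patient_id, self.equation, self.days[:n], self.values[:n])


def first_sustained_below(days, values, threshold: float, sustain_days: int = 91) -> int | None:
    """Index of the earliest confirmed sustained crossing below ``threshold``.

    A start value ``v[i] < threshold`` is confirmed by a later value
    ``v[j] < threshold`` with ``days[j] − days[i] ≥ sustain_days`` and no
    value exceeding the threshold in between.  Returns the start index, or
    None (an empty result is a value, not an error).
    """
    days = np.asarray(days)
    values = np.asarray(values)
    n = len(days)
    below = values < threshold
    for i in range(n):
        if not below[i]:
            continue
        for j in range(i + 1, n):
            if values[j] > threshold:
                break
            if below[j] and days[j] - days[i] >= sustain_days:
                return i
    return None


def first_sustained_below_date(series: EgfrSeries, threshold: float, sustain_days: int = 91):
    i = first_sustained_below(series.days, series.values, threshold, sustain_days)
    return None if i is None else day_to_date(int(series.days[i]))


def prevalent_g3_in_year(
    series: EgfrSeries, year: int, thresholds: GuidelineThresholds | None = None
) -> bool:
    """Biochemically prevalent stage G3A/G3B at the end of a calendar year.

    Uses all values dated on or before 31 December of the year.  True iff a
    qualifying pair exists (two values in [g3_low, g3_high) at least
    ``confirm_gap_days`` apart) whose start postdates every value above
    g3_high — i.e. CKD can be "resolved" by a later normal value and
    re-established by a new pair — and the patient had not already crossed
    into G4–5 before the year began (sustained-below-30 onset in an earlier
    year).  A patient progressing below 30 *during* the year remains in that
    year's G3A/G3B cohort: they are exactly the in-year "eGFR <30 only"
    referrals, and leave the cohort from the following year.

    The caller is responsible for denominator membership (≥1 creatinine in
    the year and survival through 31 December).
    """
    t = thresholds or GuidelineThresholds()
    s = series.truncated(year_end_day(year))
    if len(s) < 2:
        return False
    onset = first_sustained_below(s.days, s.values, t.g3_low, t.sustain_days)
    if onset is not None and s.days[onset] < year_start_day(year):
        return False
    above = s.values > t.g3_high
    start = int(np.max(np.nonzero(above)[0])) + 1 if above.any() else 0
    in_band = (s.values[start:] >= t.g3_low) & (s.values[start:] < t.g3_high)
    if in_band.sum() < 2:
        return False
    band_days = s.days[start:][in_band]
    return bool(band_days[-1] - band_days[0] >= t.confirm_gap_days)


def accelerated_decline_index_days(
    days, values, thresholds: GuidelineThresholds | None = None
) -> list[int]:
    """Days of every confirmed accelerated-decline index measurement.

    A pair (i, j) with 0 < days[j] − days[i] ≤ decline_window_days qualifies
    when v[j] ≤ max(v[i]·(1 − decline_rel), v[i] − decline_abs) =: L; the
    decline is sustained when a later value ≤ L occurs ≥ sustain_days after
    j with no intervening value rising above L.  j is the index date.
    """
    t = thresholds or GuidelineThresholds()
    days = np.asarray(days)
    values = np.asarray(values)
    n = len(days)
    out: list[int] = []
    for j in range(1, n):
        confirmed = False
        for i in range(j - 1, -1, -1):
            dt = days[j] - days[i]
            if dt > t.decline_window_days:
                break
            level = max(values[i] * (1.0 - t.decline_rel), values[i] - t.decline_abs)
            if values[j] > level:
                continue
            for k in range(j + 1, n):
                if values[k] > level:
                    break
                if days[k] - days[j] >= t.sustain_days and values[k] <= level:
                    confirmed = True
                    break
            if confirmed:
                break
        if confirmed:
            out.append(int(days[j]))
    return out


def accelerated_decline(series: EgfrSeries, thresholds: GuidelineThresholds | None = None):
    """(flag, index date of the earliest confirmed accelerated decline)."""
    idx = accelerated_decline_index_days(series.days, series.values, thresholds)
    if not idx:
        return False, None
    return True, day_to_date(idx[0])


def incident_ckd_onset(
    series: EgfrSeries, band: str = "g3_5", thresholds: GuidelineThresholds | None = None
):
    """Confirmed onset date of CKD in the given band, or None.

    ``g3_5`` uses the eGFR <60 threshold, ``g4_5`` eGFR <30; onset is the
    first sustained crossing (confirmed ≥ confirm_gap_days later with no
    intervening value above the threshold).
    """
    t = thresholds or GuidelineThresholds()
    if band == "g3_5":
        threshold = t.g3_high
    elif band == "g4_5":
        threshold = t.g3_low
    else:
        raise ValueError(f"band must be 'g3_5' or 'g4_5', got {band!r}")
    return first_sustained_below_date(series, threshold, t.confirm_gap_days)
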
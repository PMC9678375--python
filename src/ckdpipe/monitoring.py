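"""Annual uACR testing rates among prevalent G3A/G3B patients.

A patient counts as *tested* in a calendar year if at least one uACR value is
dated in that year (31 December inclusive).  Denominators are the year's
prevalent G3A/G3B cohort restricted to patients alive throughout the year —
patients dying in-year are excluded from numerator and denominator alike.
Rates are stratified by age band, sex, eGFR band (30–44 / 45–59, from the
mean of in-year values), diabetes, hypertension and whether CKD is coded in
the record; tested and untested groups are compared with chi-square tests for
the categorical factors and ANOVA for age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestingRate",
    "annual_testing_rate",
    "age_band",
    "stratified_testing_table",
]

AGE_BAND_EDGES = (18, 30, 40, 50, 60, 70, 80, 90)

STRATUM_FACTORS = ("age_band", "sex", "egfr_band", "diabetes", "hypertension", "ckd_coded")


@dataclass(frozen=True)
class TestingRate:
    year: int
    numerator: int
    denominator: int

    @property
    def rate(self) -> float | None:
        """Proportion tested, or None for an empty cohort (undefined rate)."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


def annual_testing_rate(tested_flags, year: int) -> TestingRate:
    """Testing rate from per-patient boolean tested flags for one year."""
    tested = np.asarray(tested_flags, dtype=bool)
    return TestingRate(year=year, numerator=int(tested.sum()), denominator=int(len(tested)))


def age_band(age_years, edges=AGE_BAND_EDGES) -> np.ndarray:
    """Decade-style age band labels, '18-29' … '90+' by default."""
    age = np.atleast_1d(np.asarray(age_years, dtype=float))
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])] + [f"{edges[-1]}+"]
    idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(labels) - 1)
    return np.asarray(labels, dtype=object)[idx]


def egfr_band(mean_egfr, split: float = 45.0) -> np.ndarray:
    mean_egfr = np.atleast_1d(np.asarray(mean_egfr, dtype=float))
    return np.where(mean_egfr < split, "30-44", "45-59").astype(object)


def stratified_testing_table(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-stratum testing rates plus tested-vs-untested comparisons.

    ``records`` has one row per patient-year with columns ``tested`` (bool),
    ``age`` (years) and the stratum factors ``age_band``, ``sex``,
    ``egfr_band``, ``diabetes``, ``hypertension``, ``ckd_coded``.  Returns a
    table with one row per (factor, stratum) — n, tested, rate — and a dict
    of tests: a chi-square p-value per categorical factor and an ANOVA
    p-value for age.  Strata with zero members are simply absent.
    """
    if len(records) == 0:
        raise ValueError("stratified_testing_table requires at least one record")
    rows = []
    tests: dict = {}
    tested = records["tested"].to_numpy(dtype=bool)
    for factor in STRATUM_FACTORS:
        grouped = records.groupby(factor, observed=True, sort=True)["tested"]
        for stratum, grp in grouped:
            n = int(len(grp))
            k = int(grp.sum())
            rows.append(
                {"factor": factor, "stratum": str(stratum), "n": n, "tested": k, "rate": k / n}
            )
        counts = grouped.agg(["sum", "count"])
        table = np.column_stack([counts["sum"], counts["count"] - counts["sum"]])
        if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
            tests[factor] = {"chi2": None, "p": None}
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            tests[factor] = {"chi2": float(chi2), "p": float(p)}
    ages_tested = records.loc[records["tested"], "age"].to_numpy(dtype=float)
    ages_untested = records.loc[~records["tested"], "age"].to_numpy(dtype=float)
    if len(ages_tested) >= 2 and len(ages_untested) >= 2:
        f_stat, p = stats.f_oneway(ages_tested, ages_untested)
        tests["age"] = {"anova_f": float(f_stat), "p": float(p)}
    else:
        tests["age"] = {"anova_f": None, "p": None}
    tests["age"]["median_tested"] = float(np.median(ages_tested)) if len(ages_tested) else None
    tests["age"]["median_untested"] = (
        float(np.median(ages_untested)) if len(ages_untested) else None
    )
    overall_rate = float(tested.mean())
    return pd.DataFrame(rows), {"tests": tests, "overall_rate": overall_rate}
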